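import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import petrepro as pp
from petrepro.phantom import Phantom, LesionTruth
from petrepro.quantify import (Category, categorize_tbr, coefficient_of_variation,
                               consensus_call, patient_positive, percent_agreement,
                               suv_max, suv_mean, tbr, visual_positivity_rule,
                               TbrRecord)
from petrepro.roi import ROI, RoiError


def uniform_phantom(value, shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0)):
    act = np.full(shape, float(value))
    return Phantom(act, np.zeros(shape, dtype=np.int16), spacing, [])


CENTER_ROI = ROI("probe", "sphere", (16.0, 16.0, 16.0), (6.0, 6.0, 6.0))


class TestSuv:
    def test_uniform_region_reads_exact_value(self):
        ph = uniform_phantom(1.14)
        assert suv_max(ph, CENTER_ROI) == 1.14
        assert suv_mean(ph, CENTER_ROI) == pytest.approx(1.14)
        assert suv_mean(uniform_phantom(0.80), CENTER_ROI) == pytest.approx(0.80)

    def test_zero_phantom(self):
        ph = uniform_phantom(0.0)
        assert suv_max(ph, CENTER_ROI) == 0.0

    def test_hot_voxel_dominates(self):
        ph = uniform_phantom(1.0)
        ph.activity[8, 8, 8] = 3.7
        assert suv_max(ph, CENTER_ROI) == 3.7

    def test_two_voxel_mean(self):
        ph = uniform_phantom(0.0, shape=(8, 8, 8))
        ph.activity[2, 2, 2] = 1.0
        ph.activity[3, 2, 2] = 2.0
        # box spanning exactly the two voxel centres
        roi = ROI("pair", "box", (6.0, 5.0, 5.0), (2.0, 0.9, 0.9))
        assert suv_mean(ph, roi) == pytest.approx(1.5)
        assert suv_max(ph, roi) == 2.0

    def test_empty_roi_names_region(self, blurred_phantom):
        roi = ROI("mystery", "sphere", (1e4, 1e4, 1e4), (1.0, 1.0, 1.0))
        with pytest.raises(RoiError, match="mystery"):
            suv_max(blurred_phantom, roi)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_mean_never_exceeds_max(self, seed):
        rng = np.random.default_rng(seed)
        ph = Phantom(rng.gamma(2.0, 0.5, size=(12, 12, 12)),
                     np.zeros((12, 12, 12), np.int16), (2.0, 2.0, 2.0), [])
        center = tuple(rng.uniform(6, 18, 3))
        roi = ROI("r", "ellipsoid", center, tuple(rng.uniform(2, 8, 3)))
        assert suv_mean(ph, roi) <= suv_max(ph, roi) + 1e-12


class TestTbr:
    def test_identity_and_arithmetic(self):
        assert tbr(1.14, 1.14) == pytest.approx(1.0)
        assert tbr(2.28, 1.14) == pytest.approx(2.0)
        assert tbr(0.0, 1.14) == 0.0

    def test_zero_background_names_region(self):
        with pytest.raises(ZeroDivisionError, match="left_atrium"):
            tbr(1.0, 0.0, "left_atrium")

    def test_monotone_in_numerator(self):
        values = [tbr(s, 1.14) for s in np.linspace(0, 3, 10)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_record_consistency(self):
        rec = TbrRecord.from_measurements(1.254, 1.14, "left_atrium")
        assert rec.tbr == pytest.approx(1.1)
        assert rec.category is Category.BLOOD_POOL


class TestCategorization:
    @pytest.mark.parametrize("value,expected", [
        (0.0, Category.BELOW), (0.85, Category.BELOW), (0.8999, Category.BELOW),
        (0.9, Category.BLOOD_POOL), (1.0, Category.BLOOD_POOL),
        (1.1, Category.BLOOD_POOL),
        (1.1001, Category.ABOVE), (1.25, Category.ABOVE), (5.0, Category.ABOVE),
    ])
    def test_threshold_bands(self, value, expected):
        assert categorize_tbr(value) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize_tbr(-0.1)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.0, 10.0, allow_nan=False))
    def test_partition_is_total_and_monotone(self, value):
        cat = categorize_tbr(value)
        order = {Category.BELOW: 0, Category.BLOOD_POOL: 1, Category.ABOVE: 2}
        assert cat in order
        # monotone nondecreasing in TBR
        assert order[categorize_tbr(value + 0.25)] >= order[cat]

    def test_serialises_lowercase(self):
        assert str(Category.BLOOD_POOL) == "blood_pool"


class TestCoV:
    def test_constant_samples(self):
        assert coefficient_of_variation([1.0, 1.0, 1.0]) == 0.0

    def test_hand_arithmetic(self):
        # SD of {0.9, 1.1} is 0.141421 (n-1), mean 1.0 -> 14.142%
        assert coefficient_of_variation([0.9, 1.1]) == pytest.approx(14.142, abs=1e-3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        assert coefficient_of_variation([2 * c, 2 * c, 4 * c]) == pytest.approx(
            coefficient_of_variation([2.0, 2.0, 4.0]), rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestCalls:
    @pytest.mark.parametrize("calls,expected", [
        ((False, False, False), False), ((True, False, False), False),
        ((False, True, False), False), ((False, False, True), False),
        ((True, True, False), True), ((True, False, True), True),
        ((False, True, True), True), ((True, True, True), True),
    ])
    def test_consensus_truth_table(self, calls, expected):
        assert consensus_call(calls) is expected

    def test_consensus_arity(self):
        with pytest.raises(ValueError):
            consensus_call([True, False])

    def test_patient_positive(self):
        assert patient_positive([False, False, True, False]) is True
        assert patient_positive([False] * 18) is False
        assert patient_positive([True] * 18) is True
        with pytest.raises(ValueError):
            patient_positive([])

    @pytest.mark.parametrize("extent,plaque,expected", [
        (6.0, True, True), (4.0, True, False), (5.0, True, False),
        (6.0, False, False),
    ])
    def test_visual_rule_five_mm_strict(self, extent, plaque, expected):
        lesion = LesionTruth(1, segment=1, center=(0, 0, 0), diameter_mm=extent,
                             true_amplitude=1.5)
        assert visual_positivity_rule(lesion, plaque) is expected


class TestPercentAgreement:
    def test_identical_and_complementary(self):
        a = [True, False, True]
        assert percent_agreement(a, a) == 100.0
        assert percent_agreement(a, [not x for x in a]) == 0.0

    def test_thirteen_of_fourteen(self):
        a = [True] * 14
        b = [True] * 13 + [False]
        assert percent_agreement(a, b) == pytest.approx(92.857, abs=1e-3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_agreement([True], [True, False])
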