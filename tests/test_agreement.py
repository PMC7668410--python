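import numpy as np
import pandas as pd
import pytest

import petrepro as pp
from petrepro.agreement import (NestedVarianceModel, LimitsOfAgreement,
                                ConcordanceModel, IdentifiabilityError,
                                DegenerateOutcomeWarning, interpret_kappa,
                                bc_bootstrap_ci, paired_differences, InstabilityError)

from conftest import balanced_nested_data, anova_components, two_observer_table


class TestNestedReml:
    def test_constant_response_all_zero_components(self):
        table, _ = balanced_nested_data(4, 3, 2, 1, 1, 1, seed=0)
        table["y"] = 7.25
        fit = pp.fit_nested_reml(table, "y")
        assert fit.var_patient == fit.var_segment == fit.var_residual == 0.0
        assert fit.mean == 7.25

    def test_matches_anova_oracle_on_balanced_design(self):
        table, y = balanced_nested_data(4, 3, 2, 4.0, 1.0, 0.25, seed=7)
        fit = pp.fit_nested_reml(table, "y")
        vp, vs, ve = anova_components(y)
        assert fit.var_patient == pytest.approx(vp, rel=1e-6)
        assert fit.var_segment == pytest.approx(vs, rel=1e-6)
        assert fit.var_residual == pytest.approx(ve, rel=1e-6)

    def test_zero_patient_variance_estimated_at_boundary(self):
        table, _ = balanced_nested_data(500, 3, 2, 0.0, 0.5, 0.5, seed=21)
        fit = pp.fit_nested_reml(table, "y")
        assert 0.0 <= fit.var_patient < 0.02
        assert fit.var_segment > 0.3

    def test_confounded_factor_raises_named_error(self):
        table, _ = balanced_nested_data(6, 2, 2, 1, 1, 1, seed=1)
        table["site"] = "s" + table["patient_id"].astype(str)
        with pytest.raises(IdentifiabilityError, match="site"):
            pp.fit_nested_reml(table, "y", ("site",))

    def test_fixed_effect_levels_sum_to_zero(self):
        d = pp.SimDesign(n_patients=40, scan_effects=(0.05, -0.05),
                         observer_effects=(0.02, 0.0, -0.02),
                         prevalence=0.0, frac_mi=0.0, positive_delta=0.0, seed=5)
        table = pp.simulate_measurements(d)
        fit = pp.fit_nested_reml(table, "tbr_max", ("observer_id", "scan", "study"))
        for factor, levels in fit.fixed_effects.items():
            assert sum(levels.values()) == pytest.approx(0.0, abs=1e-9)
        assert fit.fixed_effects["scan"]["1"] == pytest.approx(0.05, abs=0.02)

    def test_row_order_invariance(self):
        table, _ = balanced_nested_data(8, 4, 3, 2.0, 1.0, 0.5, seed=3)
        fit1 = pp.fit_nested_reml(table, "y")
        shuffled = table.sample(frac=1.0, random_state=42).reset_index(drop=True)
        fit2 = pp.fit_nested_reml(shuffled, "y")
        assert fit2.var_patient == pytest.approx(fit1.var_patient, rel=1e-6)
        assert fit2.var_segment == pytest.approx(fit1.var_segment, rel=1e-6)
        assert fit2.var_residual == pytest.approx(fit1.var_residual, rel=1e-6)

    def test_summary_renders(self):
        table, _ = balanced_nested_data(4, 3, 2, 1.0, 0.5, 0.25, seed=2)
        text = NestedVarianceModel(table, "y").fit().summary()
        assert "var(patient)" in text and "REML" in text


class TestLimitsOfAgreement:
    def test_constant_differences_degenerate(self):
        diffs = pd.DataFrame({"patient_id": np.repeat(np.arange(10), 3),
                              "segment_id": np.tile(np.arange(3), 10),
                              "diff": 0.3})
        res = pp.mixed_loa(diffs)
        assert res.bias == pytest.approx(0.3)
        assert res.loa_lower == pytest.approx(0.3)
        assert res.loa_upper == pytest.approx(0.3)

    def test_limits_symmetric_about_bias(self):
        table, _ = balanced_nested_data(30, 5, 2, 0.02, 0.01, 0.01, mean=0.05, seed=9)
        res = pp.mixed_loa(table.rename(columns={"y": "diff"}))
        assert res.loa_upper - res.bias == pytest.approx(res.bias - res.loa_lower)
        assert res.loa_lower <= res.bias <= res.loa_upper

    def test_shift_invariance(self):
        """Adding a constant to one scan shifts the bias by that constant and
        leaves the spread unchanged."""
        d = pp.SimDesign(n_patients=40, prevalence=0.0, frac_mi=0.0,
                         positive_delta=0.0, seed=31)
        table = pp.simulate_measurements(d)
        shifted = table.copy()
        shifted.loc[shifted["scan"] == 1, "tbr_max"] += 0.25
        res0 = pp.mixed_loa(paired_differences(table, "scan"),
                            ("study", "observer_id"))
        res1 = pp.mixed_loa(paired_differences(shifted, "scan"),
                            ("study", "observer_id"))
        assert res1.bias - res0.bias == pytest.approx(0.25, abs=1e-6)
        assert res1.sd_total == pytest.approx(res0.sd_total, rel=1e-6)

    def test_empty_pairs_raise(self):
        with pytest.raises(ValueError):
            LimitsOfAgreement(pd.DataFrame(columns=["patient_id", "segment_id", "diff"]))


class TestConcordance:
    def test_duplicated_scan_gives_perfect_agreement(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame({
            "patient_id": np.repeat(np.arange(1, 21), 5),
            "segment_id": np.tile(np.arange(1, 6), 20),
            "observer_id": 1,
            "tbr_max": np.repeat(rng.normal(1.0, 0.3, 20), 5)
            + np.tile(rng.normal(0, 0.1, 5), 20),
        })
        table = pd.concat([base.assign(scan=1), base.assign(scan=2)],
                          ignore_index=True)
        res = pp.vc_ccc(table, "scan_rescan")
        assert res.estimate == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_ccc_near_zero(self):
        rng = np.random.default_rng(5)
        n = 1000
        table = pd.DataFrame({
            "patient_id": np.tile(np.arange(1, n + 1), 2),
            "segment_id": 1,
            "observer_id": 1,
            "scan": np.repeat([1, 2], n),
            "tbr_max": rng.normal(1.0, 0.2, 2 * n),
        })
        res = pp.vc_ccc(table, "scan_rescan")
        assert res.estimate == pytest.approx(0.0, abs=0.07)

    def test_ccc_monotone_in_residual_noise(self):
        """More residual noise can only lower the expected CCC."""
        means = []
        for ve in (0.005, 0.02, 0.08):
            ests = []
            for seed in (1, 2, 3):
                d = pp.SimDesign(n_patients=60, var_residual=ve, prevalence=0.0,
                                 frac_mi=0.0, positive_delta=0.0, seed=seed)
                ests.append(pp.vc_ccc(pp.simulate_measurements(d),
                                      "scan_rescan").estimate)
            means.append(np.mean(ests))
        assert means[0] > means[1] > means[2]

    def test_mode_requires_factor(self):
        table = two_observer_table([1.0, 1.1], [1.0, 1.1])
        with pytest.raises(ValueError, match="scan"):
            ConcordanceModel(table, "scan_rescan")
        with pytest.raises(ValueError):
            ConcordanceModel(table, "nonsense")

    def test_factor_spread_two_levels(self):
        """Between-level spread of a 2-level factor with difference d is d^2/4."""
        d = pp.SimDesign(n_patients=400, scan_effects=(0.1, -0.1),
                         var_patient=0.02, var_segment=0.0, var_residual=0.005,
                         prevalence=0.0, frac_mi=0.0, positive_delta=0.0, seed=8)
        fit = pp.fit_nested_reml(pp.simulate_measurements(d), "tbr_max",
                                 ("observer_id", "study", "scan"))
        assert fit.factor_spread("scan") == pytest.approx(0.2 ** 2 / 4, rel=0.15)


class TestBinaryKappa:
    def test_identical_calls_unity(self):
        rng = np.random.default_rng(2)
        calls = rng.random(200) < 0.4
        table = pd.DataFrame({
            "patient_id": np.tile(np.repeat(np.arange(1, 21), 10), 2),
            "segment_id": np.tile(np.arange(1, 11), 40),
            "scan": 1,
            "observer_id": np.repeat([1, 2], 200),
            "visual_call": np.tile(calls, 2),
        })
        res = pp.binary_kappa_ccc(table, "interobserver")
        assert res.estimate == pytest.approx(1.0, abs=1e-6)
        assert res.kappa_label == "very good"

    def test_all_identical_calls_undefined_with_warning(self):
        table = pd.DataFrame({
            "patient_id": np.repeat([1, 2], 4),
            "segment_id": np.tile([1, 2], 4),
            "scan": 1,
            "observer_id": np.tile([1, 1, 2, 2], 2),
            "visual_call": True,
        })
        with pytest.warns(DegenerateOutcomeWarning):
            res = pp.binary_kappa_ccc(table, "interobserver")
        assert np.isnan(res.estimate)
        assert "identical" in res.reason

    def test_extreme_prevalence_warns(self):
        rng = np.random.default_rng(3)
        calls = rng.random(400) < 0.03
        table = pd.DataFrame({
            "patient_id": np.tile(np.repeat(np.arange(1, 41), 10), 2),
            "segment_id": np.tile(np.arange(1, 11), 80),
            "scan": 1,
            "observer_id": np.repeat([1, 2], 400),
            "visual_call": np.concatenate([calls, calls]),
        })
        with pytest.warns(DegenerateOutcomeWarning, match="extreme"):
            pp.binary_kappa_ccc(table, "interobserver")


class TestInterpretKappa:
    @pytest.mark.parametrize("value,label", [
        (0.15, "poor"), (0.20, "poor"), (0.21, "fair"), (0.40, "fair"),
        (0.41, "moderate"), (0.60, "moderate"), (0.61, "good"), (0.66, "good"),
        (0.80, "good"), (0.805, "good"), (0.81, "very good"), (1.0, "very good"),
        (-0.3, "poor"),
    ])
    def test_bands(self, value, label):
        assert interpret_kappa(value) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)


class TestBootstrap:
    def test_constant_estimator_degenerate_interval(self):
        table = pd.DataFrame({"patient_id": np.arange(30), "v": 1.0})
        lo, hi = bc_bootstrap_ci(lambda t: 4.2, table, n_boot=200, seed=0)
        assert lo == hi == 4.2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"patient_id": np.arange(50),
                              "v": rng.normal(size=50)})
        est = lambda t: t["v"].mean()
        assert bc_bootstrap_ci(est, table, 300, seed=5) == \
            bc_bootstrap_ci(est, table, 300, seed=5)

    def test_interval_brackets_mean_estimate(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"patient_id": np.arange(200),
                              "v": rng.normal(1.0, 1.0, 200)})
        lo, hi = bc_bootstrap_ci(lambda t: t["v"].mean(), table, 500, seed=2)
        assert lo < table["v"].mean() < hi
        assert 0.1 < hi - lo < 0.5  # roughly 2*1.96/sqrt(200)

    def test_unstable_estimator_raises(self):
        table = pd.DataFrame({"patient_id": np.arange(20), "v": 1.0})

        calls = {"n": 0}

        def estimator(t):
            calls["n"] += 1
            if calls["n"] > 1:  # fine on the full table, fails on replicates
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(InstabilityError):
            bc_bootstrap_ci(estimator, table, 200, seed=0)

    def test_small_n_boot_rejected(self):
        table = pd.DataFrame({"patient_id": [1, 2], "v": [1.0, 2.0]})
        with pytest.raises(ValueError):
            bc_bootstrap_ci(lambda t: 0.0, table, 50, seed=0)
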