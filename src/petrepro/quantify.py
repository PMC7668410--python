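"""SUV metrics, target-to-background ratios and categorisation.

Implements the uptake quantification protocol: SUV_MAX / SUV_MEAN inside
analytic regions of interest, target-to-background ratios standardised to
a background SUV_MEAN (atrial blood pool by default, a referent plaque or
great-vein blood pool as alternatives), categorisation of TBR against the
blood-pool thresholds 0.9 and 1.1, consensus adjudication (2 of 3
observers), the single-positive-segment patient rule, coefficients of
variation of repeated background measurements, and raw percent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phantom import Phantom, LesionTruth
from .roi import ROI, RoiError, roi_mask

__all__ = [
    "Category", "TbrRecord", "BACKGROUND_REGIONS",
    "suv_max", "suv_mean", "tbr", "categorize_tbr",
    "coefficient_of_variation", "consensus_call", "patient_positive",
    "visual_positivity_rule", "percent_agreement", "measure_phantom",
    "TBR_LOW_THRESHOLD", "TBR_HIGH_THRESHOLD",
]

#: TBR below 0.9 reads as below blood pool, above 1.1 as above it
TBR_LOW_THRESHOLD = 0.9
TBR_HIGH_THRESHOLD = 1.1

BACKGROUND_REGIONS = (
    "left_atrium", "right_atrium", "right_ventricle", "left_ventricle",
    "svc", "brachiocephalic", "referent_plaque",
)


class Category(str, Enum):
    """TBR relative to atrial blood pool activity."""

    BELOW = "below"
    BLOOD_POOL = "blood_pool"
    ABOVE = "above"

    def __str__(self) -> str:  # serialise as the lowercase word
        return self.value


@dataclass(frozen=True)
class TbrRecord:
    """One lesion's uptake standardised to a background region."""

    suv_max: float
    background_mean: float
    background_region: str
    tbr: float
    category: Category

    @classmethod
    def from_measurements(cls, suv_max_value: float, background_mean: float,
                          background_region: str) -> "TbrRecord":
        ratio = tbr(suv_max_value, background_mean, background_region)
        return cls(suv_max_value, background_mean, background_region,
                   ratio, categorize_tbr(ratio))


def _roi_values(phantom: Phantom, roi: ROI) -> np.ndarray:
    slices, mask = roi_mask(roi, phantom.shape, phantom.spacing)
    return phantom.activity[slices][mask]


def suv_max(phantom: Phantom, roi: ROI) -> float:
    """Maximum voxel value among voxels whose centres fall inside the ROI."""
    return float(_roi_values(phantom, roi).max())


def suv_mean(phantom: Phantom, roi: ROI) -> float:
    """Arithmetic mean of voxel values with centres inside the ROI."""
    return float(_roi_values(phantom, roi).mean())


def tbr(suv_max_value: float, background_mean: float,
        background_region: str = "left_atrium") -> float:
    """Target-to-background ratio: lesion SUV_MAX over background SUV_MEAN."""
    if background_mean <= 0:
        raise ZeroDivisionError(
            f"background SUV_MEAN in {background_region!r} must be > 0, "
            f"got {background_mean}")
    return suv_max_value / background_mean


def categorize_tbr(value: float, low: float = TBR_LOW_THRESHOLD,
                   high: float = TBR_HIGH_THRESHOLD) -> Category:
    """Categorise a TBR against blood pool: <0.9 below, 0.9-1.1 at, >1.1 above.

    Both boundaries belong to the blood-pool category (closed interval).
    """
    if value < 0:
        raise ValueError(f"TBR must be >= 0, got {value}")
    if low >= high:
        raise ValueError(f"thresholds must be ordered low < high, got {low} >= {high}")
    if value < low:
        return Category.BELOW
    if value <= high:
        return Category.BLOOD_POOL
    return Category.ABOVE


def coefficient_of_variation(samples: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample SD (n-1) / mean.

    Scale-invariant: multiplying every sample by the same positive constant
    leaves the CoV unchanged.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 2:
        raise ValueError(f"coefficient of variation needs >= 2 samples, got {x.size}")
    mean = x.mean()
    if mean <= 0:
        raise ValueError(f"coefficient of variation undefined for mean {mean} <= 0")
    return float(100.0 * x.std(ddof=1) / mean)


def consensus_call(calls: Sequence[bool]) -> bool:
    """Consensus adjudication: positive iff at least 2 of the 3 observers agree."""
    calls = list(calls)
    if len(calls) != 3:
        raise ValueError(f"consensus adjudication requires exactly 3 calls, got {len(calls)}")
    return sum(bool(c) for c in calls) >= 2


def patient_positive(segment_calls: Iterable[bool]) -> bool:
    """A single positive segment suffices for a patient-level positive call."""
    calls = [bool(c) for c in segment_calls]
    if not calls:
        raise ValueError("patient-level call requires at least one segment")
    return any(calls)


def visual_positivity_rule(lesion: LesionTruth, segment_has_plaque: bool) -> bool:
    """Ground-truth visual rule for the simulator.

    A focus counts as positive iff it lies on a plaque-bearing segment and
    its along-vessel extent exceeds 5 mm (strict inequality).  The human
    perceptual act is not modelled here; observer error belongs to the
    stochastic observer in the simulator.
    """
    return bool(segment_has_plaque) and lesion.extent_mm > 5.0


def percent_agreement(calls_a: Sequence[bool], calls_b: Sequence[bool]) -> float:
    """Raw percent agreement between two equally long boolean call lists."""
    a = np.asarray(list(calls_a), dtype=bool)
    b = np.asarray(list(calls_b), dtype=bool)
    if a.size != b.size:
        raise ValueError(f"call lists must pair up: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("percent agreement needs at least one pair")
    return float(100.0 * (a == b).mean())


def measure_phantom(phantom: Phantom, rois: Iterable[ROI]) -> pd.DataFrame:
    """Measure SUV_MAX and SUV_MEAN inside each ROI of one phantom.

    Returns one row per ROI with columns region, suv_max, suv_mean; raises
    :class:`~petrepro.roi.RoiError` (naming the region) on empty ROIs.
    """
    rows = []
    for roi in rois:
        values = _roi_values(phantom, roi)
        rows.append({"region": roi.region_label,
                     "suv_max": float(values.max()),
                     "suv_mean": float(values.mean()),
                     "n_voxels": int(values.size)})
    return pd.DataFrame(rows)
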