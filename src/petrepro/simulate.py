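"""Hierarchical measurement-table simulator with a stochastic observer model.

Generates long-format tables of per-segment target-to-background ratios
(TBR) under the nested mixed model that the agreement statistics assume:

    tbr(p, s, k, j) = mu + study(p) + scan_k + obs_j + a_p + b_{s(p)} + eps

with ``a_p ~ N(0, var_patient)``, ``b_{s(p)} ~ N(0, var_segment)`` and
``eps ~ N(0, var_residual)`` independent, and fixed-effect levels coded
sum-to-zero per factor so the grand mean stays interpretable.  Binary
visual reads are generated by flipping the segment's ground-truth
positivity with a fixed misclassification probability, independently per
observer and per scan — the simplest mechanism reproducing minor
discrepancies between reporters.

Two cohorts are supported as simulation strata: patients with stable
coronary disease (positive plaques carry a clear TBR excess) and patients
imaged after recent myocardial infarction (one culprit segment per patient
that is always truly positive but carries only a small TBR excess, so its
intensity often sits at or below blood pool).  These cohort defaults are
illustrative study conditions, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = ["SimDesign", "DesignError", "simulate_measurements",
           "save_design", "load_design", "MEASUREMENT_COLUMNS"]

#: canonical column order of a MeasurementTable
MEASUREMENT_COLUMNS = [
    "patient_id", "segment_id", "scan", "observer_id", "region",
    "suv_max", "suv_mean", "tbr_max", "visual_call",
]

#: blood-pool SUV_MEAN used to back out SUV_MAX from simulated TBR values
BLOOD_POOL_SUV = 1.14


class DesignError(ValueError):
    """Invalid simulation design."""


def _check_sum_to_zero(name, values):
    values = tuple(float(v) for v in values)
    if values and abs(sum(values)) > 1e-9:
        raise DesignError(f"{name} must sum to zero (sum-to-zero coding), got {values}")
    return values


@dataclass(frozen=True)
class SimDesign:
    """Design of a simulated reproducibility study.

    Fixed-effect level values (``study_effects``, ``scan_effects``,
    ``observer_effects``) must each sum to zero; variances are on the TBR
    scale.  ``prevalence`` is the probability that a stable-cohort segment
    is truly positive, ``observer_error`` the per-read misclassification
    probability of the visual call.  ``frac_mi`` patients form the
    recent-MI stratum, each with one culprit segment forced positive.
    ``positive_delta`` / ``culprit_delta`` are mean TBR shifts for truly
    positive stable / culprit segments.
    """

    n_patients: int = 30
    n_segments_per_patient: int = 18
    n_scans: int = 2
    n_observers: int = 3
    grand_mean: float = 0.95
    study_effects: tuple[float, ...] = (0.0, 0.0)
    scan_effects: tuple[float, ...] = (0.0, 0.0)
    observer_effects: tuple[float, ...] = (0.0, 0.0, 0.0)
    var_patient: float = 0.04
    var_segment: float = 0.02
    var_residual: float = 0.01
    prevalence: float = 0.138
    observer_error: float = 0.04
    frac_mi: float = 1.0 / 3.0
    positive_delta: float = 0.30
    culprit_delta: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_segments_per_patient < 1:
            raise DesignError("need at least one patient and one segment per patient")
        if self.n_scans < 1 or self.n_observers < 1:
            raise DesignError("need at least one scan and one observer")
        for name in ("var_patient", "var_segment", "var_residual"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        for name in ("prevalence", "observer_error", "frac_mi"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DesignError(f"{name} must lie in [0, 1]")
        object.__setattr__(self, "study_effects",
                           _check_sum_to_zero("study_effects", self.study_effects))
        object.__setattr__(self, "scan_effects",
                           _check_sum_to_zero("scan_effects", self.scan_effects))
        object.__setattr__(self, "observer_effects",
                           _check_sum_to_zero("observer_effects", self.observer_effects))
        if len(self.scan_effects) != self.n_scans:
            raise DesignError("scan_effects must have one value per scan")
        if len(self.observer_effects) != self.n_observers:
            raise DesignError("observer_effects must have one value per observer")


def simulate_measurements(design: SimDesign) -> pd.DataFrame:
    """Draw a MeasurementTable from the nested generative model.

    Returns a long-format DataFrame with one row per
    patient x segment x scan x observer, carrying ``tbr_max``, a derived
    ``suv_max`` (TBR times the blood-pool SUV_MEAN, floored at zero), the
    binary ``visual_call``, and ground-truth columns ``true_positive``,
    ``cohort`` and ``study``.  Identical designs (including seed) return
    identical tables.
    """
    rng = np.random.default_rng(design.seed)
    P, S = design.n_patients, design.n_segments_per_patient
    K, J = design.n_scans, design.n_observers

    n_mi = int(round(design.frac_mi * P))
    cohort = np.array(["mi"] * n_mi + ["stable"] * (P - n_mi))
    # studies alternate so the study factor is balanced and crossed with cohort
    n_studies = max(len(design.study_effects), 1)
    study_idx = np.arange(P) % n_studies

    a = rng.normal(0.0, np.sqrt(design.var_patient), size=P)
    b = rng.normal(0.0, np.sqrt(design.var_segment), size=(P, S))

    true_positive = rng.random((P, S)) < design.prevalence
    delta = np.where(true_positive, design.positive_delta, 0.0)
    for p in range(P):
        if cohort[p] == "mi":
            culprit = rng.integers(0, S)
            true_positive[p, culprit] = True
            delta[p, culprit] = design.culprit_delta

    eps = rng.normal(0.0, np.sqrt(design.var_residual), size=(P, S, K, J))
    flips = rng.random((P, S, K, J)) < design.observer_error

    study_eff = np.asarray(design.study_effects)[study_idx] if design.study_effects else np.zeros(P)
    tbr = (design.grand_mean
           + study_eff[:, None, None, None]
           + np.asarray(design.scan_effects)[None, None, :, None]
           + np.asarray(design.observer_effects)[None, None, None, :]
           + a[:, None, None, None]
           + b[:, :, None, None]
           + delta[:, :, None, None]
           + eps)
    visual = true_positive[:, :, None, None] ^ flips

    pp, ss, kk, jj = np.meshgrid(np.arange(P), np.arange(S), np.arange(K), np.arange(J),
                                 indexing="ij")
    table = pd.DataFrame({
        "patient_id": pp.ravel() + 1,
        "segment_id": ss.ravel() + 1,
        "scan": kk.ravel() + 1,
        "observer_id": jj.ravel() + 1,
        "region": "coronary_segment",
        "suv_max": np.maximum(tbr.ravel() * BLOOD_POOL_SUV, 0.0),
        "suv_mean": np.nan,
        "tbr_max": tbr.ravel(),
        "visual_call": visual.ravel(),
        "true_positive": true_positive[pp, ss].ravel(),
        "cohort": cohort[pp.ravel()],
        "study": np.array(["DIAMOND", "PREFFIR"])[study_idx % 2][pp.ravel()]
        if n_studies >= 2 else "DIAMOND",
    })
    return table


def save_design(design: SimDesign, path) -> None:
    payload = asdict(design)
    for key in ("study_effects", "scan_effects", "observer_effects"):
        payload[key] = [float(v) for v in payload[key]]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_design(path) -> SimDesign:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    for key in ("study_effects", "scan_effects", "observer_effects"):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(payload[key])
    return SimDesign(**payload)
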