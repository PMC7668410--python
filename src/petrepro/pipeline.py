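"""End-to-end reproducibility pipeline: simulate -> quantify -> agree -> report.

A single :func:`run_pipeline` call simulates a reproducibility study under a
:class:`RunConfig`, measures background regions on jittered phantom reads,
categorises segments against the blood-pool thresholds, fits the agreement
statistics for {all segments, visually positive plaques} x {between scans,
between observers}, and writes CSV/JSON outputs plus a run manifest.  Two
runs with identical configuration are bit-identical apart from the manifest
timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import PhantomConfig, make_phantom, Phantom
from .roi import ROI, jitter_rois
from .quantify import (categorize_tbr, consensus_call, patient_positive,
                       percent_agreement, coefficient_of_variation, measure_phantom)
from .simulate import SimDesign, simulate_measurements
from .agreement import (LimitsOfAgreement, ConcordanceModel, paired_differences,
                        interpret_kappa)

log = logging.getLogger("petrepro")

__all__ = ["RunConfig", "PipelineError", "default_background_rois",
           "background_study", "cov_by_region", "run_pipeline", "bland_altman_points",
           "plot_bland_altman"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_background_rois() -> list[ROI]:
    """Elliptical background ROIs matching the default phantom geometry.

    Atrial and ventricular ROIs sit deep inside large uniform blood pools;
    the caval and brachiocephalic ROIs sit inside narrow tubes where the
    point-spread blur creates steep gradients, and the referent-plaque ROI
    covers a small non-avid plaque — the configuration that makes atrial
    backgrounds the most reproducible reference.
    """
    return [
        ROI("left_atrium", "sphere", (120.0, 132.0, 95.0), (10.0, 10.0, 10.0)),
        ROI("right_atrium", "sphere", (72.0, 132.0, 95.0), (10.0, 10.0, 10.0)),
        ROI("left_ventricle", "ellipsoid", (120.0, 85.0, 95.0), (10.0, 14.0, 10.0)),
        ROI("right_ventricle", "ellipsoid", (72.0, 80.0, 95.0), (8.0, 12.0, 8.0)),
        ROI("svc", "ellipsoid", (72.0, 158.0, 95.0), (4.0, 8.0, 4.0)),
        ROI("brachiocephalic", "ellipsoid", (84.0, 170.0, 112.0), (8.0, 3.0, 3.0)),
        ROI("referent_plaque", "sphere", (106.0, 56.0, 95.0), (4.0, 4.0, 4.0)),
        ROI("coronary_lesion", "sphere", (120.0, 52.0, 95.0), (5.0, 5.0, 5.0)),
    ]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run.

    ``thresholds`` are the blood-pool TBR category boundaries (low < high);
    ``jitter_sigma_mm`` the SD of interobserver ROI displacement;
    ``noise_sd`` / ``scan_scale_sd`` / ``patient_scale_sd`` the measurement
    noise, per-scan calibration and between-patient activity variability of
    the phantom study; ``n_boot`` the bootstrap replicate count for CCC
    confidence intervals.
    """

    design: SimDesign = field(default_factory=SimDesign)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    thresholds: tuple[float, float] = (0.9, 1.1)
    jitter_sigma_mm: float = 1.0
    noise_sd: float = 0.05
    scan_scale_sd: float = 0.04
    patient_scale_sd: float = 0.08
    n_background_patients: int | None = None
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self):
        low, high = self.thresholds
        if not low < high:
            raise ValueError(f"thresholds must be ordered low < high, got {self.thresholds}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["study_effects"] = list(d["design"]["study_effects"])
        d["design"]["scan_effects"] = list(d["design"]["scan_effects"])
        d["design"]["observer_effects"] = list(d["design"]["observer_effects"])
        d["phantom"]["shape"] = list(d["phantom"]["shape"])
        d["phantom"]["spacing"] = list(d["phantom"]["spacing"])
        d["phantom"]["lesions"] = [dict(l, center=list(l["center"]))
                                   for l in d["phantom"]["lesions"]]
        d["thresholds"] = list(d["thresholds"])
        return d

    def hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# phantom background reproducibility study

def background_study(config: RunConfig, n_patients: int | None = None,
                     rois: list[ROI] | None = None) -> pd.DataFrame:
    """Simulate repeated background reads on the digital phantom.

    One clean blurred phantom is shared by all patients; each patient gets
    a global activity scale (between-patient variability), each scan a
    calibration scale and fresh measurement noise, and each observer-scan
    read an independently jittered copy of the ROI set.  Returns a long
    table with columns patient_id, scan, observer_id, region, suv_max,
    suv_mean.
    """
    if n_patients is None:
        n_patients = config.n_background_patients or config.design.n_patients
    if rois is None:
        rois = default_background_rois()
    base = make_phantom(config.phantom, seed=config.seed)
    clean = base.activity
    rng = np.random.default_rng(config.seed)
    rows = []
    for p in range(1, n_patients + 1):
        patient_scale = max(rng.normal(1.0, config.patient_scale_sd), 0.1)
        for k in range(1, config.design.n_scans + 1):
            scan_scale = max(rng.normal(1.0, config.scan_scale_sd), 0.1)
            vol = clean * (patient_scale * scan_scale)
            if config.noise_sd > 0:
                vol = vol + rng.normal(0.0, config.noise_sd, size=clean.shape)
            scan_phantom = Phantom(vol, base.labels, base.spacing, base.lesions)
            for j in range(1, config.design.n_observers + 1):
                read_rois = jitter_rois(rois, config.jitter_sigma_mm,
                                        seed=int(rng.integers(0, 2**31 - 1)))
                meas = measure_phantom(scan_phantom, read_rois)
                meas.insert(0, "observer_id", j)
                meas.insert(0, "scan", k)
                meas.insert(0, "patient_id", p)
                rows.append(meas)
    return pd.concat(rows, ignore_index=True)


def cov_by_region(background: pd.DataFrame, value_col: str = "suv_mean") -> pd.DataFrame:
    """Coefficient of variation of repeated background reads.

    The CoV is computed per patient per region across all scan x observer
    replicates, then summarised as mean +/- SD across patients (the
    reporting convention for background reproducibility).  Returns
    ``(per_patient, summary)`` DataFrames.
    """
    per_patient = (background.groupby(["region", "patient_id"])[value_col]
                   .apply(lambda v: coefficient_of_variation(v.to_numpy()))
                   .rename("cov_pct").reset_index())
    summary = (per_patient.groupby("region")["cov_pct"]
               .agg(cov_mean_pct="mean", cov_sd_pct="std", n_patients="count")
               .reset_index())
    return per_patient, summary


# ---------------------------------------------------------------------------
# categorisation and agreement assembly

def consensus_table(table: pd.DataFrame) -> pd.DataFrame:
    """Consensus visual calls and mean-TBR categories per patient/segment/scan."""
    def _consensus(calls):
        calls = list(calls)
        if len(calls) == 3:
            return consensus_call(calls)
        return bool(2 * int(np.sum(calls)) > len(calls))  # majority fallback

    agg = {"consensus": ("visual_call", _consensus), "tbr_mean": ("tbr_max", "mean")}
    if "cohort" in table.columns:
        agg["cohort"] = ("cohort", "first")
    return (table.groupby(["patient_id", "segment_id", "scan"])
            .agg(**agg).reset_index())


def category_frequencies(cons: pd.DataFrame, thresholds=(0.9, 1.1)) -> pd.DataFrame:
    """Frequency of TBR categories among consensus-positive segments, by cohort."""
    low, high = thresholds
    pos = cons[cons["consensus"]].copy()
    pos["category"] = [str(categorize_tbr(max(t, 0.0), low, high)) for t in pos["tbr_mean"]]
    freq = (pos.groupby(["cohort", "category"]).size().rename("n_segments")
            .reset_index())
    total = pos.groupby("cohort").size().rename("n_total")
    freq = freq.merge(total, on="cohort")
    freq["fraction"] = freq["n_segments"] / freq["n_total"]
    return freq


def _agreement_block(table: pd.DataFrame, n_boot: int, seed: int) -> dict:
    """LoA + CCC between scans and between observers, plus binary kappa."""
    out = {}
    diff_scan = paired_differences(table, "scan")
    loa_scan = LimitsOfAgreement(diff_scan, "diff",
                                 ("study", "observer_id")).fit()
    ccc_scan = ConcordanceModel(table, "scan_rescan").fit(n_boot=n_boot, seed=seed)
    out["between_scans"] = {
        "bias": loa_scan.bias, "loa_lower": loa_scan.loa_lower,
        "loa_upper": loa_scan.loa_upper, "sd_total": loa_scan.sd_total,
        "n_pairs": loa_scan.n_pairs,
        "ccc": ccc_scan.estimate, "ccc_ci": [ccc_scan.ci_lower, ccc_scan.ci_upper],
    }
    diff_obs = paired_differences(table, "observer")
    loa_obs = LimitsOfAgreement(diff_obs, "diff", ("scan", "observer_pair")).fit()
    ccc_obs = ConcordanceModel(table, "interobserver").fit(n_boot=n_boot, seed=seed + 1)
    kappa = ConcordanceModel(table, "interobserver", "visual_call",
                             binary=True).fit(n_boot=n_boot, seed=seed + 2)
    out["between_observers"] = {
        "bias": loa_obs.bias, "loa_lower": loa_obs.loa_lower,
        "loa_upper": loa_obs.loa_upper, "sd_total": loa_obs.sd_total,
        "n_pairs": loa_obs.n_pairs,
        "ccc": ccc_obs.estimate, "ccc_ci": [ccc_obs.ci_lower, ccc_obs.ci_upper],
        "kappa_visual": kappa.estimate,
        "kappa_ci": [kappa.ci_lower, kappa.ci_upper],
        "kappa_label": kappa.kappa_label,
    }
    return out


def agreement_report(table: pd.DataFrame, n_boot: int, seed: int) -> dict:
    """Agreement statistics for all segments and for visually positive plaques."""
    cons = consensus_table(table)
    pos_keys = cons.loc[cons.groupby(["patient_id", "segment_id"])["consensus"]
                        .transform("any"), ["patient_id", "segment_id"]].drop_duplicates()
    report = {"all_segments": _agreement_block(table, n_boot, seed)}
    pos_table = table.merge(pos_keys, on=["patient_id", "segment_id"])
    if pos_table["patient_id"].nunique() >= 2:
        report["visually_positive"] = _agreement_block(pos_table, n_boot, seed + 10)
    else:
        report["visually_positive"] = {"note": "fewer than 2 patients with positive plaques"}

    # per-segment and per-patient between-scan agreement on the consensus call
    wide = cons.pivot_table(index=["patient_id", "segment_id"], columns="scan",
                            values="consensus", aggfunc="first").dropna()
    scans = sorted(c for c in wide.columns)
    if len(scans) >= 2:
        report["percent_agreement_scans_segments"] = percent_agreement(
            wide[scans[0]].astype(bool), wide[scans[1]].astype(bool))
        per_patient = wide.reset_index().groupby("patient_id")[scans[:2]].any()
        report["percent_agreement_scans_patients"] = percent_agreement(
            per_patient[scans[0]], per_patient[scans[1]])
    return report


# ---------------------------------------------------------------------------
# Bland-Altman

def bland_altman_points(table: pd.DataFrame, comparison: str = "scan",
                        response: str = "tbr_max"):
    """(mean, difference) points plus the mixed-effects bias and limits.

    ``comparison='scan'`` pairs scan 1 minus scan 2 per patient/segment/
    observer; ``comparison='observer'`` pairs lower- minus higher-indexed
    observers per patient/segment/scan.  Returns ``(points, loa)`` where
    ``points`` has columns ``mean`` and ``diff`` and ``loa`` carries the
    overlay bias and 95% limits from the mixed-effects model.
    """
    diffs = paired_differences(table, comparison, response)
    fixed = ("study", "observer_id") if comparison == "scan" else ("scan", "observer_pair")
    loa = LimitsOfAgreement(diffs, "diff", fixed).fit()
    return diffs[["mean", "diff"]].assign(**{
        c: diffs[c] for c in diffs.columns if c in ("observer_id", "observer_pair", "scan")
    }), loa


def plot_bland_altman(points: pd.DataFrame, loa, path) -> None:
    """Scatter of (mean, difference) with bias and 95% limit overlays."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(points["mean"], points["diff"], s=12, alpha=0.4, edgecolors="none")
    ax.axhline(loa.bias, color="red", lw=1.2, label=f"bias {loa.bias:.3f}")
    for y in (loa.loa_lower, loa.loa_upper):
        ax.axhline(y, color="grey", lw=1.0, ls="--")
    ax.set_xlabel("mean of paired TBR$_{max}$")
    ax.set_ylabel("difference")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration

def _jsonify(obj):
    """Make a report JSON-strict: tuples to lists, non-finite floats to None."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # preserve intermediates, name the stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate -> quantify -> agree and write the report tree.

    Writes ``measurements.csv``, ``background_reads.csv``,
    ``cov_summary.csv``, ``category_frequencies.csv``,
    ``agreement.json`` and ``manifest.json`` under ``out_dir`` and returns
    the report dictionary.  Deterministic given the configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    low, high = config.thresholds

    log.info("stage simulate: %d patients", config.design.n_patients)
    table = _stage("simulate")(simulate_measurements)(config.design)
    table.to_csv(out / "measurements.csv", index=False)

    log.info("stage quantify: phantom background study")
    background = _stage("quantify")(background_study)(config)
    background.to_csv(out / "background_reads.csv", index=False)
    per_patient_cov, cov_summary = _stage("quantify")(cov_by_region)(background)
    per_patient_cov.to_csv(out / "cov_per_patient.csv", index=False)
    cov_summary.to_csv(out / "cov_summary.csv", index=False)

    log.info("stage categorize")
    cons = _stage("categorize")(consensus_table)(table)
    freq = _stage("categorize")(category_frequencies)(cons, (low, high))
    freq.to_csv(out / "category_frequencies.csv", index=False)

    log.info("stage agree: B=%d", config.n_boot)
    agree = _stage("agree")(agreement_report)(table, config.n_boot, config.seed)
    agree = _jsonify(agree)
    with open(out / "agreement.json", "w") as fh:
        json.dump(agree, fh, indent=2, allow_nan=False)

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    report = {"config_hash": manifest["config_hash"],
              "cov_summary": cov_summary, "category_frequencies": freq,
              "agreement": agree}
    return report


def format_agreement_table(agree: dict) -> str:
    """Text table mirroring the scans/observers x all/positive layout."""
    rows = []
    for subset in ("all_segments", "visually_positive"):
        block = agree.get(subset, {})
        for comp in ("between_scans", "between_observers"):
            d = block.get(comp)
            if not isinstance(d, dict):
                continue
            rows.append({
                "subset": subset, "comparison": comp,
                "bias": round(d["bias"], 3),
                "loa": f"{d['loa_lower']:.2f} to {d['loa_upper']:.2f}",
                "ccc": round(d["ccc"], 3),
                "kappa": round(d["kappa_visual"], 3) if "kappa_visual" in d else "",
                "label": d.get("kappa_label", "") or "",
            })
    return pd.DataFrame(rows).to_string(index=False)
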