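"""Reproducibility statistics for nested measurement tables.

The measurement model throughout is a two-level nested linear mixed model

    y = X beta + a_patient + b_segment(patient) + eps,

with independent zero-mean Gaussian random effects for patient and for
segment nested within patient, fitted by restricted maximum likelihood
(REML) with nonnegativity-constrained variance components and sum-to-zero
coded fixed factors (observer, scan, study).  On top of the fitted
components the module provides:

* mixed-effects limits of agreement for paired differences (the bias from
  a random-effects-only model, the spread from the fixed-factor-adjusted
  model, limits at bias +/- 1.96 * total SD);
* variance-components concordance correlation coefficients (CCC) for
  scan-rescan and interobserver agreement, where the between-level spread
  of the relevant fixed factor enters the denominator;
* a kappa-type statistic obtained by running the same CCC machinery on the
  binary visual read (valid when the positive proportion is not extreme);
* bias-corrected percentile bootstrap confidence intervals that resample
  patients with replacement so segments travel with their patient.

The REML objective is profiled over the fixed effects and the residual
variance, leaving a 2-parameter problem in the variance ratios
``gamma = sigma^2_component / sigma^2_residual``; the nested block
structure admits closed-form inversion via two stacked rank-one Woodbury
updates, so each objective evaluation costs O(#segments) after a single
pass over the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "IdentifiabilityError", "ConvergenceError", "InstabilityError", "DegenerateOutcomeWarning",
    "VarianceComponents", "NestedVarianceModel", "fit_nested_reml",
    "LoaResult", "LimitsOfAgreement", "mixed_loa", "paired_differences",
    "CccResult", "ConcordanceModel", "vc_ccc", "binary_kappa_ccc",
    "interpret_kappa", "bc_bootstrap_ci",
]

LOA_MULTIPLIER = 1.96  # 95% limits; large-sample normal convention


class IdentifiabilityError(ValueError):
    """A fixed factor is confounded with another term of the design."""


class ConvergenceError(RuntimeError):
    """The REML optimiser failed to converge from every initialisation."""


class InstabilityError(RuntimeError):
    """The bootstrap estimator failed on too many replicates."""


class DegenerateOutcomeWarning(UserWarning):
    """The binary outcome carries no variance or an extreme proportion."""


# ---------------------------------------------------------------------------
# design construction

def _sum_to_zero_columns(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n_levels - 1 columns."""
    X = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    colnames: list
    factor_slices: dict          # factor -> (slice into X, level names)
    patient_codes: np.ndarray
    seg_codes: np.ndarray        # nested patient-segment codes
    seg_sizes: np.ndarray
    seg_patient: np.ndarray      # patient code of each segment
    n_patients: int
    drop_patient: bool = False
    drop_segment: bool = False


def _build_design(table: pd.DataFrame, response: str, fixed_factors,
                  patient_col: str, segment_col: str) -> _Design:
    if response not in table.columns:
        raise KeyError(f"response column {response!r} not in table")
    y = pd.to_numeric(table[response], errors="raise").to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {response!r} contains non-finite values")
    n = y.size
    if n == 0:
        raise ValueError("empty measurement table")

    patient_codes, _ = pd.factorize(table[patient_col], sort=True)
    seg_raw, _ = pd.factorize(table[segment_col], sort=True)
    # nested segment code: unique per (patient, segment)
    key = patient_codes.astype(np.int64) * (int(seg_raw.max()) + 1) + seg_raw
    _, seg_codes = np.unique(key, return_inverse=True)
    n_patients = int(patient_codes.max()) + 1
    n_segments = int(seg_codes.max()) + 1
    seg_sizes = np.bincount(seg_codes, minlength=n_segments).astype(float)
    # patient code owning each segment
    first = np.zeros(n_segments, dtype=int)
    first[seg_codes] = np.arange(seg_codes.size)  # any row of the segment works
    seg_patient = patient_codes[first]

    cols = [np.ones((n, 1))]
    colnames = ["mean"]
    factor_slices = {}
    for factor in fixed_factors:
        if factor not in table.columns:
            raise IdentifiabilityError(f"fixed factor {factor!r} not in table")
        codes, levels = pd.factorize(table[factor], sort=True)
        if len(levels) < 2:
            factor_slices[factor] = (slice(0, 0), [str(l) for l in levels])
            continue
        # a factor whose levels biject with patients is confounded with the
        # patient random effect: between-patient information cannot separate them
        lvl_by_patient = pd.crosstab(codes, patient_codes).to_numpy() > 0
        if len(levels) >= n_patients and lvl_by_patient.sum(axis=1).max() == 1:
            raise IdentifiabilityError(
                f"fixed factor {factor!r} is confounded with patient")
        start = sum(c.shape[1] for c in cols)
        cols.append(_sum_to_zero_columns(codes, len(levels)))
        factor_slices[factor] = (slice(start, start + len(levels) - 1),
                                 [str(l) for l in levels])
        colnames += [f"{factor}[{l}]" for l in levels[:-1]]
        X = np.hstack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise IdentifiabilityError(
                f"fixed factor {factor!r} is confounded with earlier design terms")
    X = np.hstack(cols)
    if n <= X.shape[1]:
        raise ValueError("fewer observations than fixed-effect parameters")

    d = _Design(y, X, colnames, factor_slices, patient_codes, seg_codes,
                seg_sizes, seg_patient, n_patients)
    # degenerate nesting: drop components that the data cannot identify
    patient_sizes = np.bincount(patient_codes, minlength=n_patients)
    if n_segments == n_patients:
        d.drop_segment = True       # one segment per patient: b aliases a
    if seg_sizes.max() == 1:
        d.drop_segment = True       # one row per segment: b aliases eps
    if patient_sizes.max() == 1:
        d.drop_patient = True       # one row per patient: a aliases eps
        d.drop_segment = True
    return d


# ---------------------------------------------------------------------------
# profiled REML

class _RemlKernel:
    """Profiled restricted likelihood in the variance ratios (gamma_p, gamma_s)."""

    def __init__(self, d: _Design):
        self.d = d
        B = np.column_stack([d.X, d.y])
        self.q = d.X.shape[1]
        self.n = d.y.size
        self.G0 = B.T @ B
        # per-segment and per-patient sufficient statistics
        S = d.seg_sizes.size
        self.segsum = np.zeros((S, self.q + 1))
        for j in range(self.q + 1):
            self.segsum[:, j] = np.bincount(d.seg_codes, weights=B[:, j], minlength=S)
        self.ns = d.seg_sizes
        self.seg_patient = d.seg_patient
        self.P = d.n_patients

    def neg2_reml(self, gamma_p: float, gamma_s: float):
        ns, segsum = self.ns, self.segsum
        denom_s = 1.0 + gamma_s * ns
        ws = gamma_s / denom_s
        G = self.G0 - (segsum * ws[:, None]).T @ segsum       # B' A^-1 B
        logdet = float(np.sum(np.log(denom_s)))
        if gamma_p > 0:
            psum = np.zeros((self.P, self.q + 1))
            contrib = segsum / denom_s[:, None]
            for j in range(self.q + 1):
                psum[:, j] = np.bincount(self.seg_patient, weights=contrib[:, j],
                                         minlength=self.P)
            t_p = np.bincount(self.seg_patient, weights=ns / denom_s, minlength=self.P)
            wp = gamma_p / (1.0 + gamma_p * t_p)
            G = G - (psum * wp[:, None]).T @ psum
            logdet += float(np.sum(np.log1p(gamma_p * t_p)))
        M = G[:self.q, :self.q]
        c = G[:self.q, self.q]
        yy = G[self.q, self.q]
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            raise IdentifiabilityError("singular fixed-effects design (X'V^-1X not PD)")
        beta = np.linalg.solve(L.T, np.linalg.solve(L, c))
        rss = max(yy - c @ beta, 1e-300)
        dof = self.n - self.q
        sigma2 = rss / dof
        val = (dof * (np.log(sigma2) + 1.0 + np.log(2.0 * np.pi))
               + logdet + 2.0 * float(np.sum(np.log(np.diag(L)))))
        return val, beta, sigma2


def _optimize_reml(kernel: _RemlKernel, drop_patient: bool, drop_segment: bool,
                   loglik_tol: float = 1e-8, max_iter: int = 5000):
    """Minimise the profiled -2*REML over the active variance ratios.

    Ratios are parametrised as theta^2 so the nonnegativity constraint is
    implicit and the zero boundary is attainable.  Three dispersed
    initialisations are tried and the best restricted likelihood kept.
    """
    active = [k for k, dropped in enumerate((drop_patient, drop_segment)) if not dropped]
    GAMMA_MAX = 1e8  # ratio cap: exact-fit limit, keeps X'V^-1X well conditioned

    def unpack(theta):
        g = [0.0, 0.0]
        for k, th in zip(active, np.atleast_1d(theta)):
            g[k] = min(float(th) ** 2, GAMMA_MAX)
        return g

    if not active:
        val, beta, sigma2 = kernel.neg2_reml(0.0, 0.0)
        return (0.0, 0.0), beta, sigma2, -0.5 * val, True

    def objective(theta):
        try:
            return kernel.neg2_reml(*unpack(theta))[0]
        except (IdentifiabilityError, np.linalg.LinAlgError):
            return np.inf  # numerically degenerate corner; steer away

    starts = [np.sqrt([0.5] * len(active)),
              np.sqrt([5.0] + [0.5] * (len(active) - 1)),
              np.sqrt([0.02] * len(active))]
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": min(loglik_tol * 0.1, 1e-11),
                     "maxiter": max_iter, "maxfev": max_iter})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    if not converged:
        raise ConvergenceError(
            f"REML did not converge from any initialisation: {best.message} "
            f"(best -2lR {best.fun:.6g} after {best.nit} iterations)")
    gamma = unpack(best.x)
    val, beta, sigma2 = kernel.neg2_reml(*gamma)
    return tuple(gamma), beta, sigma2, -0.5 * val, True


# ---------------------------------------------------------------------------
# model / results

@dataclass
class VarianceComponents:
    """REML estimates of the nested variance-components model.

    ``fixed_effects`` maps each factor to its per-level estimates under
    sum-to-zero coding (levels sum to zero); ``mean`` is the global mean.
    """

    var_patient: float
    var_segment: float
    var_residual: float
    mean: float
    fixed_effects: dict
    loglik_restricted: float
    n_obs: int
    n_patients: int
    n_segments: int
    converged: bool = True
    dropped: tuple = ()

    @property
    def var_total(self) -> float:
        return self.var_patient + self.var_segment + self.var_residual

    def factor_spread(self, factor: str) -> float:
        """Between-level spread of a fixed factor: sum_l (beta_l - mean_l)^2 / L.

        Population-variance form over the L levels; for two levels that
        differ by d this equals d^2/4.  Zero for absent or single-level
        factors.
        """
        levels = self.fixed_effects.get(factor, {})
        if len(levels) < 2:
            return 0.0
        b = np.array(list(levels.values()), dtype=float)
        return float(np.mean((b - b.mean()) ** 2))

    def summary(self) -> str:
        lines = ["Nested variance components (REML)",
                 "=" * 42,
                 f"{'observations':<28}{self.n_obs}",
                 f"{'patients':<28}{self.n_patients}",
                 f"{'segments (nested)':<28}{self.n_segments}",
                 f"{'restricted log-likelihood':<28}{self.loglik_restricted:.4f}",
                 "-" * 42,
                 f"{'var(patient)':<28}{self.var_patient:.6g}",
                 f"{'var(segment|patient)':<28}{self.var_segment:.6g}",
                 f"{'var(residual)':<28}{self.var_residual:.6g}",
                 "-" * 42,
                 f"{'mean':<28}{self.mean:.6g}"]
        for factor, levels in self.fixed_effects.items():
            for lvl, est in levels.items():
                lines.append(f"{factor + '[' + lvl + ']':<28}{est:.6g}")
        if self.dropped:
            lines.append(f"(components fixed at 0 as unidentifiable: {', '.join(self.dropped)})")
        return "\n".join(lines)


class NestedVarianceModel:
    """Two-level nested random-effects model for a long measurement table.

    Parameters
    ----------
    data
        Long-format table with one row per measurement.
    response
        Numeric column to model (e.g. ``tbr_max``).
    fixed_factors
        Categorical columns entering as sum-to-zero fixed effects
        (e.g. ``("observer_id", "study", "scan")``); the global mean is
        always included.
    patient_col, segment_col
        Grouping columns; segments are treated as nested within patients.
    """

    def __init__(self, data: pd.DataFrame, response: str, fixed_factors=(),
                 patient_col: str = "patient_id", segment_col: str = "segment_id"):
        self.data = data
        self.response = response
        self.fixed_factors = tuple(fixed_factors)
        self.patient_col = patient_col
        self.segment_col = segment_col
        self._design = _build_design(data, response, self.fixed_factors,
                                     patient_col, segment_col)

    def fit(self, loglik_tol: float = 1e-8, max_iter: int = 5000) -> VarianceComponents:
        d = self._design
        kernel = _RemlKernel(d)
        if np.ptp(d.y) == 0.0:
            # all responses identical: every component is exactly zero
            fe = {f: {lvl: 0.0 for lvl in levels}
                  for f, (sl, levels) in d.factor_slices.items()}
            return VarianceComponents(0.0, 0.0, 0.0, float(d.y[0]), fe,
                                      np.inf, d.y.size, d.n_patients,
                                      d.seg_sizes.size, True, ())
        gamma, beta, sigma2, loglik, converged = _optimize_reml(
            kernel, d.drop_patient, d.drop_segment, loglik_tol, max_iter)
        fe = {}
        for factor, (sl, levels) in d.factor_slices.items():
            b = beta[sl]
            ests = list(b) + ([-float(np.sum(b))] if len(levels) >= 2 else [])
            if len(levels) == 1:
                ests = [0.0]
            fe[factor] = {lvl: float(e) for lvl, e in zip(levels, ests)}
        dropped = tuple(name for name, flag in
                        (("patient", d.drop_patient), ("segment", d.drop_segment)) if flag)
        return VarianceComponents(
            var_patient=gamma[0] * sigma2,
            var_segment=gamma[1] * sigma2,
            var_residual=sigma2,
            mean=float(beta[0]),
            fixed_effects=fe,
            loglik_restricted=loglik,
            n_obs=d.y.size,
            n_patients=d.n_patients,
            n_segments=d.seg_sizes.size,
            converged=converged,
            dropped=dropped)


def fit_nested_reml(table: pd.DataFrame, response: str, fixed_factors=(),
                    patient_col: str = "patient_id",
                    segment_col: str = "segment_id") -> VarianceComponents:
    """Fit the nested variance-components model by REML (functional surface)."""
    if table[patient_col].nunique() < 2:
        raise ValueError("need at least 2 patients")
    return NestedVarianceModel(table, response, fixed_factors,
                               patient_col, segment_col).fit()


# ---------------------------------------------------------------------------
# paired differences and limits of agreement

def paired_differences(table: pd.DataFrame, comparison: str = "scan",
                       response: str = "tbr_max",
                       patient_col: str = "patient_id",
                       segment_col: str = "segment_id") -> pd.DataFrame:
    """Build paired differences between scans or observers.

    Sign convention: scan 1 minus scan 2; lower-indexed observer minus
    higher-indexed observer.  Returns columns ``diff`` and ``mean`` plus
    the identifying/covariate columns; for observer comparisons an
    ``observer_pair`` factor labels each contrast.
    """
    keep = [c for c in ("study", "cohort", "true_positive") if c in table.columns]
    if comparison == "scan":
        scans = sorted(table["scan"].unique())
        if len(scans) < 2:
            raise ValueError("scan comparison needs 2 scans")
        idx = [patient_col, segment_col, "observer_id"]
        wide = table.pivot_table(index=idx + keep, columns="scan",
                                 values=response, aggfunc="first").reset_index()
        wide = wide.dropna(subset=scans[:2])
        out = wide[idx + keep].copy()
        out["diff"] = wide[scans[0]] - wide[scans[1]]
        out["mean"] = (wide[scans[0]] + wide[scans[1]]) / 2.0
    elif comparison == "observer":
        observers = sorted(table["observer_id"].unique())
        if len(observers) < 2:
            raise ValueError("observer comparison needs 2 observers")
        idx = [patient_col, segment_col, "scan"]
        wide = table.pivot_table(index=idx + keep, columns="observer_id",
                                 values=response, aggfunc="first").reset_index()
        frames = []
        for i, oa in enumerate(observers):
            for ob in observers[i + 1:]:
                sub = wide.dropna(subset=[oa, ob])
                part = sub[idx + keep].copy()
                part["observer_pair"] = f"{oa}-{ob}"
                part["diff"] = sub[oa] - sub[ob]
                part["mean"] = (sub[oa] + sub[ob]) / 2.0
                frames.append(part)
        out = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"comparison must be 'scan' or 'observer', got {comparison!r}")
    if out.empty:
        raise ValueError(f"no complete pairs for {comparison} comparison")
    return out


@dataclass
class LoaResult:
    """Mixed-effects limits of agreement for paired differences."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_total: float
    n_pairs: int
    components: VarianceComponents | None = None

    def summary(self) -> str:
        return "\n".join([
            "Mixed-effects limits of agreement",
            "=" * 42,
            f"{'pairs':<28}{self.n_pairs}",
            f"{'mean bias':<28}{self.bias:.4f}",
            f"{'total SD of differences':<28}{self.sd_total:.4f}",
            f"{'95% limits':<28}{self.loa_lower:.4f} to {self.loa_upper:.4f}",
        ])


class LimitsOfAgreement:
    """Mixed-effects limits of agreement on a paired-difference table.

    The mean bias comes from a model containing only the nested random
    effects (segment within patient); the spread comes from a second model
    that additionally adjusts for the requested fixed factors (study and
    observer for scan-rescan; scan and observer pair for interobserver).
    Limits are ``bias +/- 1.96 * sqrt(var_p + var_s + var_eps)``.
    """

    def __init__(self, diff_table: pd.DataFrame, value_col: str = "diff",
                 fixed_factors=(), patient_col: str = "patient_id",
                 segment_col: str = "segment_id"):
        if diff_table.empty:
            raise ValueError("no paired observations supplied")
        self.diff_table = diff_table
        self.value_col = value_col
        self.fixed_factors = tuple(f for f in fixed_factors if f in diff_table.columns)
        self.patient_col = patient_col
        self.segment_col = segment_col

    def fit(self) -> LoaResult:
        bias_fit = NestedVarianceModel(
            self.diff_table, self.value_col, (),
            self.patient_col, self.segment_col).fit()
        spread_fit = NestedVarianceModel(
            self.diff_table, self.value_col, self.fixed_factors,
            self.patient_col, self.segment_col).fit()
        sd_total = float(np.sqrt(spread_fit.var_total))
        bias = bias_fit.mean
        return LoaResult(bias=bias,
                         loa_lower=bias - LOA_MULTIPLIER * sd_total,
                         loa_upper=bias + LOA_MULTIPLIER * sd_total,
                         sd_total=sd_total,
                         n_pairs=len(self.diff_table),
                         components=spread_fit)


def mixed_loa(diff_table: pd.DataFrame, fixed_factors=(),
              value_col: str = "diff", patient_col: str = "patient_id",
              segment_col: str = "segment_id") -> LoaResult:
    """Mixed-effects limits of agreement (functional surface)."""
    return LimitsOfAgreement(diff_table, value_col, fixed_factors,
                             patient_col, segment_col).fit()


# ---------------------------------------------------------------------------
# concordance correlation (continuous and binary)

@dataclass
class CccResult:
    """Variance-components concordance correlation with bootstrap CI."""

    estimate: float
    ci_lower: float
    ci_upper: float
    mode: str
    outcome: str
    n_boot: int
    seed: int | None
    components: VarianceComponents | None = None
    kappa_label: str | None = None
    reason: str | None = None

    def summary(self) -> str:
        name = "kappa (VC-CCC on binary reads)" if self.outcome == "binary" else "CCC"
        lines = ["Variance-components concordance",
                 "=" * 42,
                 f"{'mode':<28}{self.mode}",
                 f"{'outcome':<28}{self.outcome}",
                 f"{name:<28}{self.estimate:.4f}"]
        if self.n_boot:
            lines.append(f"{'95% bootstrap CI':<28}{self.ci_lower:.4f} to {self.ci_upper:.4f}"
                         f"  (B={self.n_boot})")
        if self.kappa_label is not None:
            lines.append(f"{'interpretation':<28}{self.kappa_label}")
        if self.reason is not None:
            lines.append(f"note: {self.reason}")
        return "\n".join(lines)


_MODE_FACTOR = {"scan_rescan": "scan", "interobserver": "observer_id"}


class ConcordanceModel:
    """Variance-components CCC for scan-rescan or interobserver agreement.

    Fits the nested model to the raw response adjusting for observer,
    study and scan (those present in the table) and forms

        CCC = (var_p + var_s) / (var_p + var_s + phi2_A + var_eps)

    where ``phi2_A`` is the between-level spread of the scan factor
    (``mode='scan_rescan'``) or of the observer factor
    (``mode='interobserver'``).  With ``binary=True`` the same machinery
    runs on the 0/1 visual read and yields a kappa-type statistic.
    """

    def __init__(self, table: pd.DataFrame, mode: str, response: str = "tbr_max",
                 binary: bool = False, patient_col: str = "patient_id",
                 segment_col: str = "segment_id"):
        if mode not in _MODE_FACTOR:
            raise ValueError(f"mode must be one of {sorted(_MODE_FACTOR)}, got {mode!r}")
        factor = _MODE_FACTOR[mode]
        if factor not in table.columns or table[factor].nunique() < 2:
            raise ValueError(
                f"mode {mode!r} needs >= 2 levels of {factor!r} in the table")
        self.table = table
        self.mode = mode
        self.binary = binary
        self.response = response
        self.patient_col = patient_col
        self.segment_col = segment_col
        self.fixed_factors = tuple(
            f for f in ("observer_id", "study", "scan")
            if f in table.columns and table[f].nunique() >= 2)

    def _point_estimate(self, table: pd.DataFrame):
        work = table
        if self.binary:
            work = table.copy()
            work["_y"] = table[self.response].astype(float)
            response = "_y"
        else:
            response = self.response
        comps = NestedVarianceModel(work, response, self.fixed_factors,
                                    self.patient_col, self.segment_col).fit()
        phi2 = comps.factor_spread(_MODE_FACTOR[self.mode])
        denom = comps.var_patient + comps.var_segment + phi2 + comps.var_residual
        if denom == 0.0:
            return np.nan, comps
        return (comps.var_patient + comps.var_segment) / denom, comps

    def fit(self, n_boot: int = 2000, seed: int | None = None) -> CccResult:
        response_col = "visual_call" if (self.binary and self.response == "tbr_max") \
            else self.response
        outcome = "binary" if self.binary else "continuous"
        if self.binary:
            calls = self.table[response_col].astype(float)
            prop = calls.mean()
            if calls.nunique() < 2:
                warnings.warn(
                    "all binary calls identical: agreement undefined (zero total variance)",
                    DegenerateOutcomeWarning)
                return CccResult(np.nan, np.nan, np.nan, self.mode, outcome, 0, seed,
                                 None, None,
                                 reason="all calls identical; zero total variance")
            if not 0.1 <= prop <= 0.9:
                warnings.warn(
                    f"positive proportion {prop:.3f} outside [0.1, 0.9]; the "
                    "variance-components kappa is only well behaved when "
                    "proportions are not too extreme", DegenerateOutcomeWarning)
        model = self if response_col == self.response else ConcordanceModel(
            self.table, self.mode, response_col, self.binary,
            self.patient_col, self.segment_col)
        estimate, comps = model._point_estimate(model.table)
        ci_lower = ci_upper = np.nan
        if n_boot and np.isfinite(estimate):
            ci_lower, ci_upper = bc_bootstrap_ci(
                lambda t: model._point_estimate(t)[0], model.table,
                n_boot=n_boot, seed=0 if seed is None else seed,
                patient_col=self.patient_col)
        label = interpret_kappa(estimate) if self.binary and np.isfinite(estimate) else None
        return CccResult(float(estimate), float(ci_lower), float(ci_upper),
                         self.mode, outcome, int(n_boot or 0), seed, comps, label)


def vc_ccc(table: pd.DataFrame, mode: str, response: str = "tbr_max",
           n_boot: int = 0, seed: int | None = None, **kw) -> CccResult:
    """Variance-components CCC (functional surface); ``n_boot=0`` skips the CI."""
    return ConcordanceModel(table, mode, response, binary=False, **kw).fit(n_boot, seed)


def binary_kappa_ccc(table: pd.DataFrame, mode: str = "interobserver",
                     response: str = "visual_call", n_boot: int = 0,
                     seed: int | None = None, **kw) -> CccResult:
    """Kappa-type agreement: the variance-components CCC on binary reads."""
    return ConcordanceModel(table, mode, response, binary=True, **kw).fit(n_boot, seed)


def interpret_kappa(kappa: float) -> str:
    """Interpretation bands: poor <=0.20, fair to 0.40, moderate to 0.60,
    good to 0.80 (band extended to <0.81 for contiguity), very good >=0.81."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa <= 0.20:
        return "poor"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa < 0.81:
        return "good"
    return "very good"


# ---------------------------------------------------------------------------
# cluster bootstrap

def bc_bootstrap_ci(estimator, table: pd.DataFrame, n_boot: int, seed: int,
                    patient_col: str = "patient_id",
                    alpha: float = 0.05, max_failure_frac: float = 0.10):
    """95% bias-corrected percentile bootstrap CI, resampling patients.

    Patients are drawn with replacement and relabelled so each draw is an
    independent cluster (segments travel with their patient); the
    estimator is recomputed per replicate; the bias-corrected percentile
    rule places the endpoints at ``Phi(2 z0 +/- z_alpha)`` with
    ``z0 = Phi^-1(#{theta* < theta_hat} / B)``.  Deterministic given seed.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    theta_hat = float(estimator(table))
    if not np.isfinite(theta_hat):
        raise ValueError("estimator is not finite on the full table")
    codes, _ = pd.factorize(table[patient_col], sort=True)
    n_patients = codes.max() + 1
    groups = [np.flatnonzero(codes == g) for g in range(n_patients)]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        draw = rng.integers(0, n_patients, size=n_patients)
        rows = np.concatenate([groups[g] for g in draw])
        boot = table.take(rows).copy()
        boot[patient_col] = np.repeat(np.arange(n_patients),
                                      [groups[g].size for g in draw])
        try:
            reps[b] = estimator(boot)
        except Exception:
            reps[b] = np.nan
        if not np.isfinite(reps[b]):
            failures += 1
    if failures > max_failure_frac * n_boot:
        raise InstabilityError(
            f"estimator failed on {failures}/{n_boot} bootstrap replicates")
    reps = reps[np.isfinite(reps)]
    frac_below = np.mean(reps < theta_hat)
    z_alpha = norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore"):
        z0 = norm.ppf(frac_below)
    lo_p = float(norm.cdf(2.0 * z0 - z_alpha))
    hi_p = float(norm.cdf(2.0 * z0 + z_alpha))
    # (B+1)p order-statistic convention for bootstrap percentiles (quantile
    # type 6): counteracts the inward bias of linear interpolation at small B
    return (float(np.quantile(reps, lo_p, method="weibull")),
            float(np.quantile(reps, hi_p, method="weibull")))
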