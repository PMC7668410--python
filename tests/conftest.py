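import numpy as np
import pandas as pd
import pytest

import petrepro as pp


@pytest.fixture(scope="session")
def unblurred_phantom():
    return pp.make_phantom(pp.PhantomConfig(fwhm_mm=0.0), seed=0)


@pytest.fixture(scope="session")
def blurred_phantom():
    return pp.make_phantom(pp.PhantomConfig(), seed=0)


def balanced_nested_data(n_patients, n_segments, n_reps, var_p, var_s, var_e,
                         mean=10.0, seed=0):
    """Balanced nested draws: returns (long table, 3D response array)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(var_p), n_patients)
    b = rng.normal(0, np.sqrt(var_s), (n_patients, n_segments))
    y = (mean + a[:, None, None] + b[:, :, None]
         + rng.normal(0, np.sqrt(var_e), (n_patients, n_segments, n_reps)))
    p, s, r = np.meshgrid(np.arange(n_patients), np.arange(n_segments),
                          np.arange(n_reps), indexing="ij")
    table = pd.DataFrame({
        "patient_id": p.ravel() + 1,
        "segment_id": s.ravel() + 1,
        "rep": r.ravel() + 1,
        "y": y.ravel(),
    })
    return table, y


def anova_components(y):
    """Method-of-moments estimators from the balanced nested ANOVA mean squares.

    Independent closed-form oracle: expected mean squares give
    MS_E = var_e, MS_S = var_e + r*var_s, MS_P = var_e + r*var_s + s*r*var_p.
    """
    P, S, R = y.shape
    ybar_ps = y.mean(axis=2)
    ybar_p = y.mean(axis=(1, 2))
    ybar = y.mean()
    ms_e = ((y - ybar_ps[:, :, None]) ** 2).sum() / (P * S * (R - 1))
    ms_s = R * ((ybar_ps - ybar_p[:, None]) ** 2).sum() / (P * (S - 1))
    ms_p = S * R * ((ybar_p - ybar) ** 2).sum() / (P - 1)
    return (ms_p - ms_s) / (S * R), (ms_s - ms_e) / R, ms_e


def lin_ccc(x, y):
    """Lin's concordance correlation computed directly on paired vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    return 2 * sxy / (x.var(ddof=1) + y.var(ddof=1) + (x.mean() - y.mean()) ** 2)


def cohen_kappa(a, b):
    """Cohen's kappa from the 2x2 contingency table of two binary raters."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    po = (a == b).mean()
    pe = a.mean() * b.mean() + (1 - a.mean()) * (1 - b.mean())
    return (po - pe) / (1 - pe)


def two_observer_table(x, y):
    """MeasurementTable with one segment per patient read by two observers."""
    n = len(x)
    return pd.DataFrame({
        "patient_id": np.tile(np.arange(1, n + 1), 2),
        "segment_id": 1,
        "scan": 1,
        "observer_id": np.repeat([1, 2], n),
        "tbr_max": np.concatenate([x, y]),
    })
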