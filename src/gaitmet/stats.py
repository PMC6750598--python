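"""Repeated-measures correlation and condition-wise RMS errors.

The repeated-measures correlation (r_rm) quantifies the within-subject
association between two repeatedly measured variables by fitting a common
slope with a separate intercept per subject (analysis of covariance).  It
is the appropriate association measure when each subject contributes
several (speed, incline) trials, which would violate the independence
assumption of an ordinary Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RmcorrResult:
    r_rm: float
    ci95: tuple[float, float]
    slope: float
    intercepts: dict
    df: int
    n_points: int


def rmcorr(x, y, subject_ids, ci_level: float = 0.95) -> RmcorrResult:
    """Repeated-measures correlation of y on x with per-subject intercepts.

    Implemented as the ANCOVA common-slope fit: within-subject centering
    removes the subject intercepts, the common slope is the least-squares
    slope of the centered data, and r_rm is the signed square root of the
    fraction of remaining variance the slope explains.  Degrees of freedom
    are n_points - n_subjects - 1; the confidence interval uses the Fisher
    z-transform with that df.  Missing (NaN) pairs are dropped listwise;
    subjects with fewer than two points contribute an intercept only.
    """
    df_in = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                          "s": np.asarray(subject_ids)})
    df_in = df_in.dropna()
    if df_in.empty:
        raise ValueError("no complete (x, y) pairs")
    counts = df_in.groupby("s").size()
    if (counts < 2).any():
        warnings.warn(
            f"subjects with fewer than 2 points contribute intercept only: "
            f"{list(counts.index[counts < 2])}"
        )
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with at least 2 points")
    g = df_in.groupby("s")
    xc = df_in["x"] - g["x"].transform("mean")
    yc = df_in["y"] - g["y"].transform("mean")
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x is constant within every subject")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    ss_slope = slope * sxy            # variance explained by the common slope
    ss_error = syy - ss_slope
    r = np.sign(slope) * np.sqrt(ss_slope / (ss_slope + ss_error)) if syy > 0 else 0.0
    r = float(np.clip(r, -1.0, 1.0))
    n = len(df_in)
    k = df_in["s"].nunique()
    dof = n - k - 1
    # Fisher z interval with the repeated-measures degrees of freedom
    if dof > 1 and abs(r) < 1.0:
        zcrit = sps.norm.ppf(0.5 + ci_level / 2.0)
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(dof - 1)
        ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    else:
        ci = (r, r)
    means = g[["x", "y"]].mean()
    intercepts = {s: float(row["y"] - slope * row["x"]) for s, row in means.iterrows()}
    return RmcorrResult(r_rm=r, ci95=ci, slope=float(slope),
                        intercepts=intercepts, df=int(dof), n_points=int(n))


def rms_error(calc, meas, conditions) -> pd.DataFrame:
    """Per-condition RMS error between calculated and measured cost.

    ``conditions`` is a sequence of (speed, incline) per trial.  Trials
    with a missing member of the pair are dropped; an empty condition is
    omitted with a warning.  Returns a DataFrame with columns speed,
    incline, rms, n.
    """
    df = pd.DataFrame({
        "calc": np.asarray(calc, float),
        "meas": np.asarray(meas, float),
        "speed": [c[0] for c in conditions],
        "incline": [c[1] for c in conditions],
    })
    rows = []
    for (speed, incline), grp in df.groupby(["speed", "incline"]):
        grp = grp.dropna()
        if grp.empty:
            warnings.warn(f"condition ({speed}, {incline}) has no complete pairs")
            continue
        err = grp["calc"] - grp["meas"]
        rows.append({"speed": speed, "incline": incline,
                     "rms": float(np.sqrt(np.mean(err**2))), "n": len(grp)})
    return pd.DataFrame(rows)
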