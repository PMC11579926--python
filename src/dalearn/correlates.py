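"""Linking neural stimulus responses to individual learning trajectories.

Correlation-style statistics are computed with robust (Huber M-estimator)
regression rather than Pearson correlation, to blunt the influence of
outlier mice/sessions.  The goodness-of-fit statistic generalizes R^2:

    pseudoR2 = 1 - deviance(model) / deviance(null)
    r        = sign(slope) * sqrt(pseudoR2)

where deviance is the summed Huber loss of the residuals at the fit (scaled,
see :func:`robust_fit`) and the null model is an intercept-only robust fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RobustFitResult",
    "robust_fit",
    "trajectory_correlation",
    "group_ttest",
    "median_split_groups",
    "early_late_summary",
    "flip_to_contralateral",
    "bin_sessions",
    "make_lmm_table",
]

HUBER_C = 1.345  # 95% Gaussian efficiency
INITIAL_SCALE = 10.0


def _huber_rho(u: np.ndarray, c: float) -> np.ndarray:
    a = np.abs(u)
    return np.where(a <= c, 0.5 * u**2, c * a - 0.5 * c**2)


def _huber_weights(u: np.ndarray, c: float) -> np.ndarray:
    a = np.abs(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(a <= c, 1.0, c / a)
    w[~np.isfinite(w)] = 1.0
    return w


def _irls(X: np.ndarray, y: np.ndarray, c: float, scale0: float,
          max_iter: int = 200, tol: float = 1e-10):
    """Huber IRLS with MAD scale updates, returning (coef, scale)."""
    coef = np.linalg.lstsq(X, y, rcond=None)[0]
    scale = scale0
    for _ in range(max_iter):
        r = y - X @ coef
        mad = np.median(np.abs(r - np.median(r))) * 1.4826
        if mad > 0:
            scale = mad
        w = _huber_weights(r / scale, c)
        WX = X * w[:, None]
        coef_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        if np.max(np.abs(coef_new - coef)) < tol * (1 + np.max(np.abs(coef))):
            coef = coef_new
            break
        coef = coef_new
    return coef, scale


def _deviance(r: np.ndarray, scale: float, c: float) -> float:
    """Summed Huber loss at the fit, on the squared-residual scale."""
    return float(np.sum(_huber_rho(r / scale, c)) * scale**2)


@dataclass
class RobustFitResult:
    slope: float
    intercept: float
    deviance: float
    null_deviance: float
    pseudo_r2: float
    r: float
    scale: float
    n: int


def robust_fit(x: np.ndarray, y: np.ndarray, c: float = HUBER_C,
               initial_scale: float = INITIAL_SCALE) -> RobustFitResult:
    """Huber M-estimation of ``y ~ intercept + slope * x``.

    Iteratively reweighted least squares with tuning constant 1.345 and MAD
    scale re-estimation starting from ``initial_scale``.  Deviance is
    ``sum(rho(res / scale)) * scale^2`` at convergence; the null deviance
    comes from the intercept-only robust fit.  ``r = sign(slope) *
    sqrt(pseudoR2)``; a negative pseudoR2 yields ``r = NaN`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is unidentifiable")

    X = np.column_stack([np.ones_like(x), x])
    coef, scale = _irls(X, y, c, initial_scale)
    dev = _deviance(y - X @ coef, scale, c)
    coef0, scale0 = _irls(np.ones((x.size, 1)), y, c, initial_scale)
    null_dev = _deviance(y - coef0[0], scale0, c)

    if null_dev == 0.0:
        pseudo_r2 = 0.0 if dev == 0.0 else -np.inf
    else:
        pseudo_r2 = 1.0 - dev / null_dev
    if pseudo_r2 < 0:
        warnings.warn("negative pseudo-R2; r set to NaN", RuntimeWarning)
        r = np.nan
    else:
        r = float(np.sign(coef[1]) * np.sqrt(pseudo_r2))
    return RobustFitResult(slope=float(coef[1]), intercept=float(coef[0]),
                           deviance=dev, null_deviance=null_dev,
                           pseudo_r2=float(pseudo_r2), r=r,
                           scale=float(scale), n=int(x.size))


def trajectory_correlation(neural: pd.Series | np.ndarray,
                           behavioral: pd.Series | np.ndarray,
                           min_sessions: int = 3) -> float | None:
    """Robust correlation ``r`` between per-session neural and behavioral series.

    Series are aligned on their index if pandas Series are given; with fewer
    than ``min_sessions`` common sessions the mouse is excluded (returns
    None, with a logged reason).
    """
    if isinstance(neural, pd.Series) and isinstance(behavioral, pd.Series):
        joined = pd.concat([neural, behavioral], axis=1, join="inner").dropna()
        xn = joined.iloc[:, 0].to_numpy()
        yb = joined.iloc[:, 1].to_numpy()
    else:
        xn = np.asarray(neural, dtype=float)
        yb = np.asarray(behavioral, dtype=float)
        keep = np.isfinite(xn) & np.isfinite(yb)
        xn, yb = xn[keep], yb[keep]
    if xn.size < min_sessions:
        logger.info("excluding series: only %d common sessions", xn.size)
        return None
    return robust_fit(xn, yb).r


def group_ttest(per_mouse_r) -> tuple[float, float]:
    """One-sample t test of the mean per-mouse ``r`` against zero."""
    r = np.asarray([v for v in per_mouse_r if v is not None and np.isfinite(v)],
                   dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 mice")
    if np.ptp(r) == 0:
        raise ValueError("zero variance across mice; t statistic undefined")
    t, p = stats.ttest_1samp(r, 0.0)
    return float(t), float(p)


def median_split_groups(session0_metric: dict | pd.Series) -> dict:
    """Median split of mice into strong/weak responders.

    Values strictly above the cohort median are 'strong'; the median element
    itself (odd n, or ties at the median) goes to 'weak', making the split
    deterministic.  An all-equal input has no informative split and errors.
    """
    s = pd.Series(session0_metric, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 mice")
    if np.ptp(s.to_numpy()) == 0:
        raise ValueError("all values equal; no informative median split")
    med = float(s.median())
    return {k: ("strong" if v > med else "weak") for k, v in s.items()}


def early_late_summary(weights, early_window=(1, 5), late_window=(16, 20)):
    """Early bias, late stimulus asymmetry and late bias from a trajectory.

    ``weights`` is a WeightTrajectory (from the behavioral fit) or a
    DataFrame with columns session/weight/mean.  Early bias is the mean bias
    weight over sessions 1-5; late asymmetry the mean of (right - left)
    stimulus weights over sessions 16-20; windows are configurable.
    """
    table = getattr(weights, "table", weights)
    piv = table.pivot(index="session", columns="weight", values="mean")

    def _window_mean(col, lo, hi):
        want = np.arange(lo, hi + 1)
        if not np.isin(want, piv.index).all():
            raise ValueError(f"sessions {lo}-{hi} not all present")
        return float(piv.loc[want, col].mean())

    early_bias = _window_mean("bias", *early_window)
    late_r = _window_mean("right_stim", *late_window)
    late_l = _window_mean("left_stim", *late_window)
    late_bias = _window_mean("bias", *late_window)
    return {"early_bias": early_bias,
            "late_stim_asymmetry": late_r - late_l,
            "late_bias": late_bias}


def flip_to_contralateral(values, hemisphere):
    """Sign-flip rightward-positive quantities so positive = contralateral.

    A left-hemisphere recording views the right side as contralateral, so
    its values pass through; right-hemisphere values are negated.
    """
    values = np.asarray(values, dtype=float)
    if hemisphere == "left":
        return values.copy()
    if hemisphere == "right":
        return -values
    raise ValueError(f"unknown hemisphere {hemisphere!r}")


_BIN_EDGES = {"early": (1, 7), "middle": (8, 14), "late": (15, 20)}


def bin_sessions(session_index: int) -> str:
    """Training-period category: early = 1-7, middle = 8-14, late = 15-20."""
    s = int(session_index)
    if not 1 <= s <= 20:
        raise ValueError(f"session {s} outside 1-20")
    for name, (lo, hi) in _BIN_EDGES.items():
        if lo <= s <= hi:
            return name
    raise AssertionError  # unreachable


def make_lmm_table(behavior_summaries: pd.DataFrame,
                   region_metric: dict | pd.Series,
                   weight: str = "right_stim") -> pd.DataFrame:
    """Long-format table for external mixed-model tools.

    One row per mouse x session with the binned session category, the
    mean-subtracted per-mouse region metric (e.g. session-0 contrast-
    dependent stimulus response), and the behavioral weight value.
    ``behavior_summaries`` needs columns mouse/session/weight/mean.
    """
    metric = pd.Series(region_metric, dtype=float)
    metric = metric - metric.mean()
    sub = behavior_summaries[behavior_summaries["weight"] == weight]
    rows = []
    for row in sub.itertuples(index=False):
        rows.append({
            "mouse": row.mouse,
            "session": row.session,
            "session_bin": bin_sessions(row.session),
            "region_metric": float(metric.get(row.mouse, np.nan)),
            "weight_name": weight,
            "weight_value": row.mean,
        })
    return pd.DataFrame(rows)
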