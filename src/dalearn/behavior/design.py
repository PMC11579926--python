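"""Trial-level regressors for the session-evolving choice model.

The linear predictor for the probability of a rightward choice on trial ``t``
of session ``d`` is ``x_t . beta_d`` with regressor vector

    x_t = [1, x_R, -x_L, c_t]

where ``x_R``/``x_L`` are tanh-transformed stimulus contrasts (only the
presented side is nonzero), and ``c_t`` is an exponentially filtered trace of
previous choices.  Sign convention: positive ``beta_left`` means greater
sensitivity toward left choices (the left regressor enters negated), so both
stimulus weights grow positive over learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "transform_contrast",
    "transform_contrast_dalpha",
    "filter_choice_history",
    "filter_choice_history_dpi",
    "SessionDesign",
    "build_design",
]


def transform_contrast(S, alpha):
    """Saturating contrast transform ``tanh(alpha * S) / tanh(alpha)``.

    Maps contrast fractions ``S`` in [0, 1] to [0, 1], with value exactly 1 at
    full contrast for any shape ``alpha > 0``.  Large ``alpha`` saturates the
    psychometric curve below 100% contrast, which absorbs lapse-like
    flattening without explicit lapse parameters.

    Parameters
    ----------
    S : float or array
        Contrast fraction(s) in [0, 1].
    alpha : float
        Positive shape parameter.

    Returns
    -------
    float or ndarray
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return np.tanh(alpha * np.asarray(S, dtype=float)) / np.tanh(alpha)


def transform_contrast_dalpha(S, alpha):
    """Derivative of :func:`transform_contrast` with respect to ``alpha``."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    S = np.asarray(S, dtype=float)
    ta = np.tanh(alpha)
    tS = np.tanh(alpha * S)
    return (S * (1.0 - tS**2) * ta - tS * (1.0 - ta**2)) / ta**2


def filter_choice_history(choices_pm1, pi):
    """Exponentially filtered choice history ``c``.

    Recursion ``c_t = c_{t-1} + pi * (y_{t-1} - c_{t-1})`` with ``c_1 = 0``
    (no fabricated pre-session history) and choices ``y`` coded +1 = right,
    -1 = left.  ``c_t`` depends only on strictly previous choices, and
    ``|c_t| <= 1`` throughout.

    Parameters
    ----------
    choices_pm1 : array of +/-1
    pi : float in (0, 1)
        Filter update fraction (larger = faster forgetting).
    """
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must be in (0,1), got {pi}")
    y = np.asarray(choices_pm1, dtype=float)
    if y.size == 0:
        return np.zeros(0)
    # AR(1) recursion c_t = (1-pi) c_{t-1} + pi * y_{t-1}, c_1 = 0
    u = np.concatenate([[0.0], y[:-1]])
    return lfilter([pi], [1.0, -(1.0 - pi)], u)


def filter_choice_history_dpi(choices_pm1, pi, c=None):
    """Derivative ``dc/dpi`` of the history filter (same recursion order)."""
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must be in (0,1), got {pi}")
    y = np.asarray(choices_pm1, dtype=float)
    if y.size == 0:
        return np.zeros(0)
    if c is None:
        c = filter_choice_history(y, pi)
    u = np.concatenate([[0.0], y[:-1]])
    # g_t = (1-pi) g_{t-1} + (u_t - c_{t-1}), g_1 = 0
    c_prev = np.concatenate([[0.0], c[:-1]])
    return lfilter([1.0], [1.0, -(1.0 - pi)], u - c_prev)


@dataclass
class SessionDesign:
    """Design matrix and choice codings for one session.

    Attributes
    ----------
    X : ndarray, shape (n_trials, 4)
        Rows ``[1, x_R, -x_L, c_t]``.
    y : ndarray
        Choice coded 1 = right, 0 = left.
    y_pm : ndarray
        Choice coded +1 = right, -1 = left.
    """

    X: np.ndarray
    y: np.ndarray
    y_pm: np.ndarray


def build_design(trials: pd.DataFrame, alpha: float, pi: float) -> SessionDesign:
    """Assemble the per-trial regressor matrix for one session.

    ``trials`` must carry ``side``, ``contrast`` and ``choice`` columns
    (choices are needed for the history filter).  The history trace restarts
    at 0 at the start of the session.
    """
    if trials["choice"].isna().any():
        raise ValueError("missing choice mid-session; cannot build history regressor")
    side = trials["side"].to_numpy()
    S = trials["contrast"].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy()
    y = (choice == "right").astype(float)
    y_pm = 2.0 * y - 1.0

    xs = transform_contrast(S, alpha)
    is_right = side == "right"
    x_R = np.where(is_right, xs, 0.0)
    x_L = np.where(~is_right, xs, 0.0)
    c = filter_choice_history(y_pm, pi)

    X = np.column_stack([np.ones_like(xs), x_R, -x_L, c])
    return SessionDesign(X=X, y=y, y_pm=y_pm)
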