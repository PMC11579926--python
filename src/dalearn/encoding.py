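"""Event-kernel encoding model of photometry, fit by empirical-Bayes ridge.

Each task event contributes a strictly causal 1-second temporal kernel
(50 samples at 50 Hz) to the predicted signal.  Kernels are parameterized on
a raised-cosine basis; the basis-space weights are estimated by ridge
regression with the ridge strength ``gamma`` and observation noise
``sigma_f^2`` chosen by maximizing the Gaussian log marginal likelihood
(evidence).  At the optimum the posterior is

    Sigma = (sigma_f^-2 X'X + gamma I)^-1,   beta = sigma_f^-2 Sigma X' f

with the intercept column left unpenalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .events import DEFAULT_CONTRASTS, extract_events, kernel_labels

__all__ = [
    "BasisSet",
    "KernelSpec",
    "RidgeFit",
    "KernelSet",
    "make_basis",
    "detect_first_movement",
    "build_design_matrix",
    "fit_ridge_evidence",
    "reconstruct_kernels",
    "contrast_dependence",
    "model_r2",
]

N_LAGS = 50  # 1 s at 50 Hz
FS = 50.0


@dataclass
class BasisSet:
    """Raised-cosine temporal basis over the causal lag window.

    ``B`` has shape (n_lags, n_basis); bump j is
    ``0.5 * (1 + cos(pi * (t - c_j) / w))`` for ``|t - c_j| <= w``, centers
    linearly spaced over [0, n_lags - 1], width w = 2 x center spacing so
    neighbors cross at half height (columns sum to a constant away from the
    edges).
    """

    B: np.ndarray
    centers: np.ndarray
    width: float

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    @property
    def n_lags(self) -> int:
        return self.B.shape[0]


def make_basis(n_basis: int, n_lags: int = N_LAGS) -> BasisSet:
    if not 2 <= n_basis <= n_lags:
        raise ValueError(f"n_basis must be in [2, {n_lags}]")
    centers = np.linspace(0.0, n_lags - 1.0, n_basis)
    width = 2.0 * (centers[1] - centers[0]) if n_basis > 1 else float(n_lags)
    t = np.arange(n_lags, dtype=float)[:, None]
    arg = np.pi * (t - centers[None, :]) / width
    B = np.where(np.abs(arg) <= np.pi, 0.5 * (1.0 + np.cos(arg)), 0.0)
    return BasisSet(B=B, centers=centers, width=width)


def detect_first_movement(wheel_time: np.ndarray, wheel_pos: np.ndarray,
                          quiescent_end: float,
                          threshold_rad: float = 0.1):
    """First time after ``quiescent_end`` with wheel displacement > 0.1 rad.

    Displacement is measured from the wheel position at the end of the
    quiescent period (strict inequality).  Returns None if the wheel never
    crosses the threshold.
    """
    t = np.asarray(wheel_time, dtype=float)
    x = np.asarray(wheel_pos, dtype=float)
    if not (t[0] <= quiescent_end <= t[-1]):
        raise ValueError("quiescent_end outside wheel series support")
    ref = np.interp(quiescent_end, t, x)
    after = t >= quiescent_end
    crossed = after & (np.abs(x - ref) > threshold_rad)
    if not crossed.any():
        return None
    return float(t[np.argmax(crossed)])


@dataclass(frozen=True)
class KernelSpec:
    """The labeled kernel set: 40 for the full task, 8 for pre-exposure."""

    contrasts: tuple = DEFAULT_CONTRASTS
    kind: str = "full"  # "full" | "stim"

    @property
    def labels(self) -> list[str]:
        return kernel_labels(self.contrasts, kind=self.kind)

    @property
    def n_kernels(self) -> int:
        return len(self.labels)


def build_design_matrix(trials: pd.DataFrame, basis: BasisSet,
                        spec: KernelSpec, n_samples: int,
                        fs: float = FS) -> np.ndarray:
    """Design matrix: intercept plus one basis-column block per kernel.

    Each event of kernel ``k`` at sample ``s`` adds the basis (rows
    ``s .. s+n_lags-1``) into block ``k``; overlapping events sum.  Events
    are aligned to the nearest sample.
    """
    labels = spec.labels
    col_of = {lab: i for i, lab in enumerate(labels)}
    nb = basis.n_basis
    X = np.zeros((n_samples, 1 + len(labels) * nb))
    X[:, 0] = 1.0
    for t_ev, lab in extract_events(trials, kind=spec.kind):
        if lab not in col_of:
            raise ValueError(f"event label {lab!r} not in kernel spec")
        s = int(round(t_ev * fs))
        if not 0 <= s < n_samples:
            raise ValueError(f"event at {t_ev:.3f}s outside trace support")
        stop = min(s + basis.n_lags, n_samples)
        j0 = 1 + col_of[lab] * nb
        X[s:stop, j0:j0 + nb] += basis.B[:stop - s]
    return X


@dataclass
class RidgeFit:
    """Evidence-optimized ridge solution in basis space."""

    beta: np.ndarray  # (n_columns,), intercept first
    gamma: float
    sigma_f2: float
    log_evidence: float
    Sigma: np.ndarray  # posterior covariance of beta
    n_samples: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta


def _evidence_terms(eigvals, proj2, f2c, n, gamma, sigma2):
    """Log marginal likelihood of the centered ridge model, O(p).

    ``eigvals``/``proj2`` are the eigenvalues of Xc'Xc and the squared
    projections of Xc'fc on the eigenvectors; ``f2c = fc'fc``.
    """
    with np.errstate(over="ignore", divide="ignore"):
        denom = eigvals / sigma2 + gamma
        # log det(sigma2 I + Xc C Xc') with C = I/gamma, centered problem
        logdet = (n - 1) * np.log(sigma2) + np.sum(np.log(denom)
                                                   - np.log(gamma))
        quad = (f2c - np.sum(proj2 / (sigma2 * denom))) / sigma2
        return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + quad)


def fit_ridge_evidence(X: np.ndarray, f: np.ndarray,
                       gamma0: float = 1.0, sigma20: float | None = None
                       ) -> RidgeFit:
    """Empirical-Bayes ridge regression with an unpenalized intercept.

    The evidence is maximized over (log gamma, log sigma_f^2) on the
    intercept-projected (column-centered) problem; the returned ``beta`` and
    ``Sigma`` are the exact closed forms at the optimum with penalty matrix
    ``diag(0, gamma, ..., gamma)``.
    """
    f = np.asarray(f, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than design columns")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite values in the response")
    Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
    fc = f - f.mean()
    XtX = Xc.T @ Xc
    eigvals, Q = np.linalg.eigh(XtX)
    eigvals = np.maximum(eigvals, 0.0)
    proj2 = (Q.T @ (Xc.T @ fc)) ** 2
    f2c = float(fc @ fc)

    if sigma20 is None:
        sigma20 = max(float(np.var(fc)), 1e-8)

    def neg_ev(logparams):
        g, s2 = np.exp(logparams)
        val = _evidence_terms(eigvals, proj2, f2c, n, g, s2)
        return -val if np.isfinite(val) else np.inf

    best = None
    for lg0 in (np.log(gamma0), np.log(gamma0) + 4.0, np.log(gamma0) - 4.0):
        res = minimize(neg_ev, x0=[lg0, np.log(sigma20)],
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ValueError("evidence is non-finite; degenerate design matrix")
    gamma, sigma2 = map(float, np.exp(best.x))
    beta, Sigma = ridge_solution(X, f, gamma, sigma2)
    return RidgeFit(beta=beta, gamma=gamma, sigma_f2=sigma2,
                    log_evidence=float(-best.fun), Sigma=Sigma, n_samples=n)


def ridge_solution(X: np.ndarray, f: np.ndarray, gamma: float, sigma2: float,
                   penalize_intercept: bool = False):
    """Closed-form ridge posterior at fixed hyperparameters.

    Returns ``(beta, Sigma)`` with ``Sigma = (sigma2^-1 X'X + P)^-1`` and
    ``beta = sigma2^-1 Sigma X' f``; the first column is treated as the
    intercept and left unpenalized unless requested otherwise.
    """
    p = X.shape[1]
    P = np.full(p, gamma)
    if not penalize_intercept:
        P[0] = 0.0
    Sigma = np.linalg.inv(X.T @ X / sigma2 + np.diag(P))
    beta = Sigma @ (X.T @ np.asarray(f, dtype=float)) / sigma2
    return beta, Sigma


@dataclass
class KernelSet:
    """Lag-domain kernels reconstructed from a basis-space fit."""

    kernels: dict  # label -> (n_lags,)
    l2: dict  # label -> float
    fs: float = FS

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab, k in self.kernels.items():
            for i, v in enumerate(k):
                rows.append({"kernel": lab, "lag_s": i / self.fs, "value": v})
        return pd.DataFrame(rows)


def reconstruct_kernels(fit: RidgeFit, basis: BasisSet,
                        spec: KernelSpec) -> KernelSet:
    """Map basis weights back to 50-sample kernels and compute L2 norms."""
    nb = basis.n_basis
    labels = spec.labels
    expected = 1 + len(labels) * nb
    if fit.beta.size != expected:
        raise ValueError("fit is inconsistent with basis/kernel spec")
    kernels, l2 = {}, {}
    for i, lab in enumerate(labels):
        w = fit.beta[1 + i * nb:1 + (i + 1) * nb]
        k = basis.B @ w
        kernels[lab] = k
        l2[lab] = float(np.linalg.norm(k))
    return KernelSet(kernels=kernels, l2=l2, fs=FS)


def contrast_dependence(kernels: KernelSet, side: str,
                        hi: float = 1.0, lo: float = 0.0625,
                        metric: str = "diff-of-norms") -> float:
    """Contrast dependence of the stimulus response for one side.

    ``diff-of-norms`` (default): L2(highest contrast) - L2(lowest contrast).
    ``norm-of-diff``: L2 of the kernel difference.
    """
    from .events import stim_label

    k_hi = kernels.kernels.get(stim_label(side, hi))
    k_lo = kernels.kernels.get(stim_label(side, lo))
    if k_hi is None or k_lo is None:
        raise ValueError("missing stimulus kernel for contrast dependence")
    if metric == "diff-of-norms":
        return float(np.linalg.norm(k_hi) - np.linalg.norm(k_lo))
    if metric == "norm-of-diff":
        return float(np.linalg.norm(k_hi - k_lo))
    raise ValueError(f"unknown metric {metric!r}")


def model_r2(fit: RidgeFit, X: np.ndarray, f: np.ndarray,
             trials: pd.DataFrame, fs: float = FS) -> float:
    """Variance explained within trial epochs (stimulus to feedback + 1 s)."""
    f = np.asarray(f, dtype=float)
    n = f.size
    mask = np.zeros(n, dtype=bool)
    for row in trials.itertuples(index=False):
        s = int(round(row.stim_onset_time * fs))
        e = int(round((row.feedback_time + 1.0) * fs))
        mask[max(s, 0):min(e, n)] = True
    if not mask.any():
        raise ValueError("no samples fall within trial epochs")
    pred = fit.predict(X)
    resid = f[mask] - pred[mask]
    ss_res = float(resid @ resid)
    dev = f[mask] - f[mask].mean()
    ss_tot = float(dev @ dev)
    return 1.0 - ss_res / ss_tot
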