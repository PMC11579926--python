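"""Hierarchical Bernoulli GLM with session-evolving weights.

One model per mouse.  Each session ``d`` has its own 4-vector of choice
weights ``beta_d`` (bias, right-stim, left-stim, history); the prior on
``beta_d`` is a multivariate Student-t random walk centered on the previous
session's weights with a shared scale matrix ``Sigma = D Omega D`` (diagonal
scales ``sigma``, LKJ-distributed correlation ``Omega``).  Shared shape
parameters: degrees of freedom ``nu``, history time constant
``pi = Phi(lambda)`` and contrast-transform shape ``alpha = softplus(l)``.

Generative model (per mouse):

    nu      ~ Gamma(2, 0.2)
    eta     ~ Normal(0, 10)+          (LKJ concentration)
    L       ~ LKJCholesky(eta),  Omega = L L'
    sigma_i ~ Normal(0, 1)+           (i = 1..4)
    lambda  ~ Normal(0, 1),      pi    = Phi(lambda)
    l       ~ Normal(-2, 0.5),   alpha = softplus(l)
    mu_i    ~ StudentT(nu, 0, 5)
    beta_1  ~ MVStudentT(nu, mu, Sigma)
    beta_d  ~ MVStudentT(nu, beta_{d-1}, Sigma)
    p_{t,d} = logistic(x_{t,d} . beta_d),   y_{t,d} ~ Bernoulli(p_{t,d})

The density is evaluated on an unconstrained vector: logs for positive
scalars, tanh-transformed canonical partial correlations for ``L``, and a
non-centered random walk for the weights — ``beta_d = beta_{d-1} +
A eps_d`` with ``A = diag(sigma) L`` the Cholesky factor of ``Sigma`` and
``eps_d`` i.i.d. spherical multivariate Student-t innovations (the
Student-t family is elliptical, so this reproduces the MVT transitions
exactly while removing the scale-weight funnel).  The LKJ prior is
expressed directly in partial-correlation space: under the Cholesky-factor
transform the partial correlations are independent with symmetric Beta
densities on (-1, 1), shape ``eta + (K - 2 - j)/2`` for column ``j`` —
equivalent to LKJCholesky(eta) on ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, expit, gammaln, ndtr

from .design import (
    filter_choice_history,
    filter_choice_history_dpi,
    transform_contrast,
)

K = 4  # weights per session: bias, right-stim, left-stim, history
N_CORR = K * (K - 1) // 2  # free entries of the correlation Cholesky factor
N_SHARED = 2 + N_CORR + K + 2 + K  # nu, eta, corr, sigma, lambda, l, mu
WEIGHT_NAMES = ("bias", "right_stim", "left_stim", "history")

# column index of each partial-correlation entry, row-major lower triangle
_TRIL_ROWS, _TRIL_COLS = np.tril_indices(K, -1)

_LOG2 = np.log(2.0)
_LOG2PI = np.log(2.0 * np.pi)


def softplus(x):
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the per-mouse priors (defaults as in the model)."""

    nu_shape: float = 2.0
    nu_rate: float = 0.2
    eta_scale: float = 10.0  # half-Normal scale on the LKJ concentration
    sigma_scale: float = 1.0  # half-Normal scale on the diagonal scales
    lambda_loc: float = 0.0
    lambda_scale: float = 1.0
    mu_scale: float = 5.0  # Student-t scale of the initial-mean prior
    l_loc: float = -2.0
    l_scale: float = 0.5

    def __post_init__(self):
        for name in ("nu_shape", "nu_rate", "eta_scale", "sigma_scale",
                     "lambda_scale", "mu_scale", "l_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ChoiceData:
    """All sessions of one mouse, pre-arranged for fast likelihood evaluation."""

    def __init__(self, sessions: Sequence[pd.DataFrame]):
        self.n_sessions = len(sessions)
        if self.n_sessions < 1:
            raise ValueError("need at least one session")
        S, is_right, y01, ypm, sid = [], [], [], [], []
        self.session_slices = []
        start = 0
        for d, tr in enumerate(sessions):
            if len(tr) and tr["choice"].isna().any():
                raise ValueError("missing choice in session data")
            n = len(tr)
            if n:
                S.append(tr["contrast"].to_numpy(dtype=float))
                is_right.append((tr["side"].to_numpy() == "right"))
                yy = (tr["choice"].to_numpy() == "right").astype(float)
                y01.append(yy)
                ypm.append(2.0 * yy - 1.0)
                sid.append(np.full(n, d, dtype=np.intp))
            self.session_slices.append(slice(start, start + n))
            start += n
        cat = (lambda parts, dt: np.concatenate(parts).astype(dt)
               if parts else np.zeros(0, dtype=dt))
        self.S = cat(S, float)
        self.is_right = cat(is_right, bool)
        self.y01 = cat(y01, float)
        self.ypm = cat(ypm, float)
        self.sid = cat(sid, np.intp)
        self.n_trials = self.S.size
        lengths = {sl.stop - sl.start for sl in self.session_slices}
        # equal-length sessions allow one batched history-filter call
        self._ypm2d = (self.ypm.reshape(self.n_sessions, -1)
                       if len(lengths) == 1 and self.n_trials else None)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "ChoiceData":
        """Split a multi-session trial table on ``session_index`` (sorted)."""
        groups = [g.sort_values("trial_index")
                  for _, g in trials.groupby("session_index", sort=True)]
        return cls(groups)

    def history_and_dpi(self, pi):
        """History regressor and its pi-derivative, reset at session bounds."""
        from scipy.signal import lfilter

        if self._ypm2d is not None:
            y = self._ypm2d
            u = np.concatenate([np.zeros((y.shape[0], 1)), y[:, :-1]], axis=1)
            c = lfilter([pi], [1.0, -(1.0 - pi)], u, axis=1)
            c_prev = np.concatenate([np.zeros((y.shape[0], 1)), c[:, :-1]],
                                    axis=1)
            g = lfilter([1.0], [1.0, -(1.0 - pi)], u - c_prev, axis=1)
            return c.ravel(), g.ravel()
        c = np.empty(self.n_trials)
        g = np.empty(self.n_trials)
        for sl in self.session_slices:
            y = self.ypm[sl]
            cs = filter_choice_history(y, pi)
            c[sl] = cs
            g[sl] = filter_choice_history_dpi(y, pi, cs)
        return c, g


# ---------------------------------------------------------------------------
# unconstrained parameterization


def n_params(n_sessions: int) -> int:
    return N_SHARED + K * n_sessions


@dataclass
class ParamDraw:
    """Constrained-space view of one parameter draw."""

    nu: float
    eta: float
    L: np.ndarray  # (K, K) lower Cholesky factor of the correlation matrix
    sigma: np.ndarray  # (K,)
    lam: float
    l: float
    mu: np.ndarray  # (K,)
    beta: np.ndarray  # (n_sessions, K)
    pi: float = field(init=False)
    alpha: float = field(init=False)

    def __post_init__(self):
        self.pi = float(ndtr(self.lam))
        self.alpha = float(softplus(self.l))

    @property
    def Omega(self) -> np.ndarray:
        return self.L @ self.L.T

    @property
    def Sigma(self) -> np.ndarray:
        D = np.diag(self.sigma)
        return D @ self.Omega @ D


def corr_chol_from_z(z: np.ndarray) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial corrs.

    ``z`` holds the lower-triangle entries row-major; ``L[i,j] =
    z_ij * prod_{k<j} sqrt(1 - z_ik^2)`` with unit row norms.
    """
    L = np.zeros((K, K))
    L[0, 0] = 1.0
    zi = iter(z)
    for i in range(1, K):
        rem = 1.0
        for j in range(i):
            zij = next(zi)
            L[i, j] = zij * np.sqrt(rem)
            rem *= 1.0 - zij**2
        L[i, i] = np.sqrt(rem)
    return L


def _split(theta: np.ndarray, n_sessions: int):
    z = np.tanh(theta[2:2 + N_CORR])
    sigma = np.exp(theta[2 + N_CORR:2 + N_CORR + K])
    i0 = 2 + N_CORR + K
    return {
        "nu": float(np.exp(theta[0])),
        "eta": float(np.exp(theta[1])),
        "z": z,
        "sigma": sigma,
        "lam": float(theta[i0]),
        "l": float(theta[i0 + 1]),
        "mu": theta[i0 + 2:i0 + 2 + K].copy(),
        "eps": theta[N_SHARED:].reshape(n_sessions, K).copy(),
    }


def beta_from_innovations(mu, A, eps):
    """Session weights from non-centered innovations: cumulative A eps."""
    return mu[None, :] + np.cumsum(eps @ A.T, axis=0)


def unpack(theta: np.ndarray, n_sessions: int) -> ParamDraw:
    """Map an unconstrained vector to constrained parameters."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != n_params(n_sessions):
        raise ValueError("parameter vector has wrong length")
    s = _split(theta, n_sessions)
    L = corr_chol_from_z(s["z"])
    A = s["sigma"][:, None] * L
    beta = beta_from_innovations(s["mu"], A, s["eps"])
    return ParamDraw(nu=s["nu"], eta=s["eta"], L=L, sigma=s["sigma"],
                     lam=s["lam"], l=s["l"], mu=s["mu"], beta=beta)


def pack(nu, eta, z_corr, sigma, lam, l, mu, beta) -> np.ndarray:
    """Inverse of :func:`unpack` from constrained values.

    ``beta`` (n_sessions, K) is converted to innovation coordinates using
    the scale factor implied by ``sigma`` and ``z_corr``.
    """
    z_corr = np.asarray(z_corr, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    mu = np.asarray(mu, dtype=float)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    A = sigma[:, None] * corr_chol_from_z(z_corr)
    prev = np.vstack([mu, beta[:-1]])
    eps = np.linalg.solve(A, (beta - prev).T).T
    return np.concatenate([
        [np.log(nu), np.log(eta)], np.arctanh(z_corr),
        np.log(sigma), [lam, l], mu, eps.ravel(),
    ])


# ---------------------------------------------------------------------------
# joint log density and gradient


def log_density_and_grad(theta: np.ndarray, data: ChoiceData,
                         prior: PriorConfig = PriorConfig()):
    """Joint log density (with all normalizing constants) and its gradient.

    Returns ``(logp, grad)`` where ``grad`` is with respect to the
    unconstrained vector ``theta``; includes the log-Jacobians of the
    transforms so the density is a proper density over ``theta``.
    """
    D = data.n_sessions
    theta = np.asarray(theta, dtype=float)
    s = _split(theta, D)
    nu, eta, sigma, lam, l = s["nu"], s["eta"], s["sigma"], s["lam"], s["l"]
    mu, eps, z = s["mu"], s["eps"], s["z"]
    L = corr_chol_from_z(z)
    A = sigma[:, None] * L
    beta = beta_from_innovations(mu, A, eps)
    pi_ = float(ndtr(lam))
    alpha = float(softplus(l))

    grad = np.zeros_like(theta)
    logp = 0.0

    # --- priors on shared scalars (with Jacobians of log/tanh transforms) ---
    # nu ~ Gamma(shape, rate), sampled as log nu
    a, b = prior.nu_shape, prior.nu_rate
    logp += a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(nu) - b * nu \
        + np.log(nu)
    g_lognu = (a - 1.0) - b * nu + 1.0
    # eta ~ halfNormal(eta_scale), sampled as log eta
    se = prior.eta_scale
    logp += _LOG2 - 0.5 * _LOG2PI - np.log(se) - 0.5 * (eta / se) ** 2 \
        + np.log(eta)
    g_logeta = -(eta / se) ** 2 + 1.0
    # sigma ~ halfNormal(sigma_scale), sampled as log sigma
    ss = prior.sigma_scale
    logp += np.sum(_LOG2 - 0.5 * _LOG2PI - np.log(ss)
                   - 0.5 * (sigma / ss) ** 2 + np.log(sigma))
    g_logsigma = -(sigma / ss) ** 2 + 1.0
    # lambda ~ Normal, l ~ Normal
    logp += (-0.5 * _LOG2PI - np.log(prior.lambda_scale)
             - 0.5 * ((lam - prior.lambda_loc) / prior.lambda_scale) ** 2)
    g_lam = -(lam - prior.lambda_loc) / prior.lambda_scale**2
    logp += (-0.5 * _LOG2PI - np.log(prior.l_scale)
             - 0.5 * ((l - prior.l_loc) / prior.l_scale) ** 2)
    g_l = -(l - prior.l_loc) / prior.l_scale**2

    # --- LKJ prior via independent partial correlations ---
    # column j entry: z ~ BetaSym(eta + (K-2-j)/2) on (-1,1); the tanh
    # Jacobian merges to give density exp(a_j * log(1-z^2) - const) in y-space
    a_lkj = eta + (K - 2.0 - _TRIL_COLS) / 2.0
    with np.errstate(divide="ignore"):  # |z| -> 1 is a valid -inf boundary
        log1mz2 = np.log1p(-z**2)
    logp += np.sum(a_lkj * log1mz2 - (2.0 * a_lkj - 1.0) * _LOG2
                   - betaln(a_lkj, a_lkj))
    g_y_corr = -2.0 * a_lkj * z  # d/dy of each term (y = arctanh z)
    g_logeta += eta * np.sum(log1mz2 - 2.0 * _LOG2
                             - 2.0 * digamma(a_lkj) + 2.0 * digamma(2.0 * a_lkj))

    # --- mu ~ StudentT(nu, 0, mu_scale), elementwise ---
    sm = prior.mu_scale
    qm = (mu / sm) ** 2
    logp += np.sum(gammaln((nu + 1) / 2) - gammaln(nu / 2)
                   - 0.5 * np.log(nu * np.pi) - np.log(sm)
                   - 0.5 * (nu + 1) * np.log1p(qm / nu))
    g_mu = -(nu + 1.0) * mu / (sm**2 * (nu + qm))
    dnu_mu = np.sum(0.5 * digamma((nu + 1) / 2) - 0.5 * digamma(nu / 2)
                    - 0.5 / nu - 0.5 * np.log1p(qm / nu)
                    + 0.5 * (nu + 1) * qm / (nu * (nu + qm)))
    g_lognu += nu * dnu_mu

    # --- innovations ~ spherical multivariate Student-t(nu), i.i.d. ---
    q = np.einsum("dk,dk->d", eps, eps)
    logp += float(np.sum(gammaln((nu + K) / 2) - gammaln(nu / 2)
                         - 0.5 * K * np.log(nu * np.pi)
                         - 0.5 * (nu + K) * np.log1p(q / nu)))
    w = (nu + K) / (nu + q)
    g_eps = -w[:, None] * eps
    dnu_tr = np.sum(0.5 * digamma((nu + K) / 2) - 0.5 * digamma(nu / 2)
                    - 0.5 * K / nu - 0.5 * np.log1p(q / nu)
                    + 0.5 * (nu + K) * q / (nu * (nu + q)))
    g_lognu += nu * dnu_tr

    # --- Bernoulli likelihood ---
    if data.n_trials:
        # shared tanh terms for the transform and its alpha-derivative
        ta = np.tanh(alpha)
        tS = np.tanh(alpha * data.S)
        xs = tS / ta
        c, dc_dpi = data.history_and_dpi(pi_)
        B = beta[data.sid]  # (n_trials, K) gather once
        xr = np.where(data.is_right, xs, 0.0)
        xl = xs - xr
        psi = B[:, 0] + B[:, 1] * xr - B[:, 2] * xl + B[:, 3] * c
        logp += float(np.sum(data.y01 * psi - np.logaddexp(0.0, psi)))
        e = data.y01 - expit(psi)  # d loglik / d psi
        g_beta = np.empty((D, K))
        g_beta[:, 0] = np.bincount(data.sid, weights=e, minlength=D)
        g_beta[:, 1] = np.bincount(data.sid, weights=e * xr, minlength=D)
        g_beta[:, 2] = np.bincount(data.sid, weights=-e * xl, minlength=D)
        g_beta[:, 3] = np.bincount(data.sid, weights=e * c, minlength=D)
        # back-propagate through beta_d = mu + A * cumsum(eps)
        g_mu += g_beta.sum(axis=0)
        G_rev = np.cumsum(g_beta[::-1], axis=0)[::-1]  # sum_{d >= j} g_beta_d
        g_eps += G_rev @ A
        # d beta_d / d A_{kl} = cumulative eps in column l at row k:
        # G_A[k, l] = sum_d g_beta[d, k] * cumsum(eps)[d, l]
        G_A = np.tril(g_beta.T @ np.cumsum(eps, axis=0))
        g_logsigma += np.sum(G_A * L, axis=1) * sigma
        G_L = sigma[:, None] * G_A
        idx = 0
        for i in range(1, K):
            rem = 1.0
            zrow = z[idx:idx + i]
            Grow = G_L[i]
            Lrow = L[i]
            for m in range(i):
                zim = zrow[m]
                tail = float(np.dot(Grow[m + 1:i + 1], Lrow[m + 1:i + 1]))
                g_y_corr[idx + m] += (Grow[m] * np.sqrt(rem)
                                      * (1.0 - zim**2) - zim * tail)
                rem *= 1.0 - zim**2
            idx += i
        # alpha via the contrast transform (right adds, left subtracts)
        dxs = (data.S * (1.0 - tS**2) * ta - tS * (1.0 - ta**2)) / ta**2
        beta_stim = np.where(data.is_right, B[:, 1], -B[:, 2])
        g_l += float(np.sum(e * beta_stim * dxs)) * expit(l)
        # pi via the history filter
        phi_lam = np.exp(-0.5 * lam * lam) / np.sqrt(2.0 * np.pi)
        g_lam += float(np.sum(e * beta[data.sid, 3] * dc_dpi)) * phi_lam

    # --- assemble gradient vector ---
    grad[0] = g_lognu
    grad[1] = g_logeta
    grad[2:2 + N_CORR] = g_y_corr
    grad[2 + N_CORR:2 + N_CORR + K] = g_logsigma
    i0 = 2 + N_CORR + K
    grad[i0] = g_lam
    grad[i0 + 1] = g_l
    grad[i0 + 2:i0 + 2 + K] = g_mu
    grad[N_SHARED:] = g_eps.ravel()
    if not np.isfinite(logp):
        return -np.inf, grad
    return float(logp), grad


def log_density(theta: np.ndarray, data: ChoiceData,
                prior: PriorConfig = PriorConfig()) -> float:
    """Joint log density of the unconstrained parameter vector."""
    return log_density_and_grad(theta, data, prior)[0]


def initial_point(data: ChoiceData, prior: PriorConfig = PriorConfig(),
                  rng: np.random.Generator | None = None,
                  jitter: float = 0.5) -> np.ndarray:
    """A reasonable unconstrained starting point, optionally jittered."""
    theta = pack(nu=5.0, eta=2.0, z_corr=np.zeros(N_CORR),
                 sigma=np.full(K, 0.3), lam=0.0, l=prior.l_loc,
                 mu=np.zeros(K), beta=np.zeros((data.n_sessions, K)))
    if rng is not None and jitter > 0:
        theta = theta + jitter * rng.uniform(-1.0, 1.0, size=theta.size)
    return theta


def _session_map_weights(data: ChoiceData, alpha: float, pi: float,
                         prior_sd: float = 2.0):
    """Per-session ridge-logistic MAP weights and total log likelihood."""
    xs = transform_contrast(data.S, alpha)
    c, _ = data.history_and_dpi(pi)
    betas = np.zeros((data.n_sessions, K))
    total = 0.0
    lam_r = 1.0 / prior_sd**2
    for d, sl in enumerate(data.session_slices):
        n = sl.stop - sl.start
        if n == 0:
            continue
        right = data.is_right[sl]
        X = np.column_stack([np.ones(n),
                             np.where(right, xs[sl], 0.0),
                             -np.where(~right, xs[sl], 0.0),
                             c[sl]])
        y = data.y01[sl]
        b = np.zeros(K)
        for _ in range(25):
            p = expit(X @ b)
            g = X.T @ (y - p) - lam_r * b
            H = (X * (p * (1 - p))[:, None]).T @ X + lam_r * np.eye(K)
            step = np.linalg.solve(H, g)
            b += step
            if np.abs(step).max() < 1e-8:
                break
        betas[d] = b
        p = expit(X @ b)
        total += float(np.sum(y * np.log(p + 1e-12)
                              + (1 - y) * np.log1p(-p + 1e-12)))
    return betas, total


def initial_point_from_data(data: ChoiceData,
                            prior: PriorConfig = PriorConfig(),
                            rng: np.random.Generator | None = None,
                            jitter: float = 0.1) -> np.ndarray:
    """Data-driven starting point: a coarse penalized profile over the shape
    parameters with per-session MAP weights.

    Scans a grid of (alpha, pi), keeps the pair maximizing session-MAP
    likelihood plus the shape priors, and initializes the weight trajectory
    at the per-session MAP fits.  Greatly shortens warmup when the
    posterior of ``alpha`` sits far from its prior mode.
    """
    if data.n_trials < 10 * max(1, data.n_sessions):
        return initial_point(data, prior, rng=rng, jitter=max(jitter, 0.2))
    best = None
    for l_try in np.linspace(-3.0, 3.5, 12):
        alpha = float(softplus(l_try))
        for lam_try in (-0.5, 0.0, 0.5):
            pi_try = float(ndtr(lam_try))
            betas, ll = _session_map_weights(data, alpha, pi_try)
            score = (ll
                     - 0.5 * ((l_try - prior.l_loc) / prior.l_scale) ** 2
                     - 0.5 * (lam_try / prior.lambda_scale) ** 2)
            if best is None or score > best[0]:
                best = (score, l_try, lam_try, betas)
    _, l0, lam0, betas = best
    diffs = np.diff(betas, axis=0)
    sigma0 = (np.clip(diffs.std(axis=0), 0.05, 1.0) if len(diffs)
              else np.full(K, 0.3))
    theta = pack(nu=5.0, eta=2.0, z_corr=np.zeros(N_CORR), sigma=sigma0,
                 lam=lam0, l=l0, mu=betas[0], beta=betas)
    if rng is not None and jitter > 0:
        theta = theta + jitter * rng.uniform(-1.0, 1.0, size=theta.size)
    return theta
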