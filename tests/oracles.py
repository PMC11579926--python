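"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (explicit loops, scipy.stats calls,
no shared code with the package's vectorized implementations) so it can
serve as an oracle.
"""

import numpy as np
from scipy import stats
from scipy.special import expit, ndtr


def softplus(x):
    return np.log1p(np.exp(x))


def chol_corr_naive(z_vals, K=4):
    """Cholesky factor of a correlation matrix from partial correlations."""
    L = np.zeros((K, K))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, K):
        rem = 1.0
        for j in range(i):
            L[i, j] = z_vals[idx] * np.sqrt(rem)
            rem = rem * (1.0 - z_vals[idx] ** 2)
            idx += 1
        L[i, i] = np.sqrt(rem)
    return L


def log_density_naive(theta, sessions, K=4):
    """Brute-force joint log density of the session-evolving choice model.

    ``sessions`` is a list of dicts with keys side (list of 'left'/'right'),
    contrast (list of floats) and choice (list of 'left'/'right').
    Matches the model's unconstrained parameterization (non-centered
    innovations for the weight random walk) term by term, but through
    scipy.stats distributions and per-trial loops.
    """
    theta = np.asarray(theta, dtype=float)
    D = len(sessions)
    n_corr = K * (K - 1) // 2
    t_nu, t_eta = theta[0], theta[1]
    y_corr = theta[2:2 + n_corr]
    t_sigma = theta[2 + n_corr:2 + n_corr + K]
    i0 = 2 + n_corr + K
    lam, l = theta[i0], theta[i0 + 1]
    mu = theta[i0 + 2:i0 + 2 + K]
    eps = theta[i0 + 2 + K:].reshape(D, K)

    nu, eta, sigma = np.exp(t_nu), np.exp(t_eta), np.exp(t_sigma)
    pi_ = float(ndtr(lam))
    alpha = float(softplus(l))

    lp = 0.0
    # priors with transform Jacobians
    lp += stats.gamma.logpdf(nu, a=2.0, scale=1 / 0.2) + t_nu
    lp += stats.halfnorm.logpdf(eta, scale=10.0) + t_eta
    for i in range(K):
        lp += stats.halfnorm.logpdf(sigma[i], scale=1.0) + t_sigma[i]
    lp += stats.norm.logpdf(lam, 0.0, 1.0)
    lp += stats.norm.logpdf(l, -2.0, 0.5)
    # LKJ prior as independent shifted Betas on the partial correlations,
    # including the tanh Jacobian
    z = np.tanh(y_corr)
    cols = [j for i in range(1, K) for j in range(i)]
    for zv, j in zip(z, cols):
        a = eta + (K - 2 - j) / 2.0
        lp += stats.beta.logpdf((zv + 1) / 2, a, a) - np.log(2.0)
        lp += np.log1p(-zv**2)  # d tanh
    # initial-mean prior
    for i in range(K):
        lp += stats.t.logpdf(mu[i], df=nu, loc=0.0, scale=5.0)
    # non-centered session random walk: spherical Student-t innovations
    for d in range(D):
        lp += stats.multivariate_t.logpdf(eps[d], loc=np.zeros(K),
                                          shape=np.eye(K), df=nu)
    # implied session weights
    L = chol_corr_naive(z, K)
    A = np.diag(sigma) @ L
    beta = np.zeros((D, K))
    prev = mu
    for d in range(D):
        beta[d] = prev + A @ eps[d]
        prev = beta[d]
    # Bernoulli likelihood, trial by trial
    for d, sess in enumerate(sessions):
        c = 0.0
        for side, S, choice in zip(sess["side"], sess["contrast"],
                                   sess["choice"]):
            x = np.tanh(alpha * S) / np.tanh(alpha)
            xr = x if side == "right" else 0.0
            xl = x if side == "left" else 0.0
            p = expit(beta[d, 0] + beta[d, 1] * xr - beta[d, 2] * xl
                      + beta[d, 3] * c)
            y = 1.0 if choice == "right" else 0.0
            lp += y * np.log(p) + (1 - y) * np.log(1 - p)
            c = c + pi_ * ((2 * y - 1) - c)
    return lp
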