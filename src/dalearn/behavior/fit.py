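"""Posterior inference and summaries for the session-evolving choice model."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .design import transform_contrast
from .model import (
    ChoiceData,
    PriorConfig,
    WEIGHT_NAMES,
    initial_point_from_data,
    log_density_and_grad,
    n_params,
    softplus,
)
from .nuts import NutsConfig, sample_nuts

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "WeightTrajectory",
    "fit_posterior",
    "summarize_weights",
    "predict_psychometric",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings (defaults: 4 chains of 500 warmup + 500 kept draws)."""

    chains: int = 4
    warmup: int = 500
    draws: int = 500
    target_accept: float = 0.9
    max_treedepth: int = 10
    seed: int = 0


@dataclass
class PosteriorDraws:
    """Posterior draws across chains, in both raw and constrained space.

    ``theta`` has shape (chains, draws, dim).  Constrained arrays are
    flattened over chains where noted.  ``diagnostics`` holds divergence
    counts and split-Rhat / bulk-ESS for the shared scalars.
    """

    theta: np.ndarray
    n_sessions: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        ch, dr, _ = self.theta.shape
        flat = self.theta.reshape(ch * dr, -1)
        D = self.n_sessions
        from .model import (N_CORR, K, N_SHARED, beta_from_innovations,
                            corr_chol_from_z)
        i0 = 2 + N_CORR + K
        self.nu = np.exp(flat[:, 0])
        self.eta = np.exp(flat[:, 1])
        self.sigma = np.exp(flat[:, 2 + N_CORR:2 + N_CORR + K])
        self.pi = ndtr(flat[:, i0])
        self.alpha = softplus(flat[:, i0 + 1])
        self.mu = flat[:, i0 + 2:i0 + 2 + K]
        eps = flat[:, N_SHARED:].reshape(-1, D, K)
        z = np.tanh(flat[:, 2:2 + N_CORR])
        self.beta = np.empty_like(eps)
        for i in range(flat.shape[0]):
            A = self.sigma[i][:, None] * corr_chol_from_z(z[i])
            self.beta[i] = beta_from_innovations(self.mu[i], A, eps[i])

    @property
    def n_chains(self):
        return self.theta.shape[0]

    @property
    def n_draws(self):
        return self.theta.shape[1]


def _scalar_diagnostics(theta: np.ndarray, n_sessions: int) -> dict:
    """Split-Rhat and bulk ESS for the shared scalar parameters via arviz."""
    import arviz as az
    from .model import N_CORR, K

    i0 = 2 + N_CORR + K
    named = {
        "log_nu": theta[:, :, 0],
        "log_eta": theta[:, :, 1],
        "lambda": theta[:, :, i0],
        "l": theta[:, :, i0 + 1],
    }
    if theta.shape[0] < 2:  # split-Rhat needs at least two chains
        return {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=named)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    return (
        {f"rhat_{k}": float(rhat[k].values) for k in named}
        | {f"ess_{k}": float(ess[k].values) for k in named}
    )


def fit_posterior(data: ChoiceData | pd.DataFrame,
                  prior: PriorConfig = PriorConfig(),
                  sampler: SamplerConfig = SamplerConfig()) -> PosteriorDraws:
    """Sample the per-mouse posterior with NUTS.

    Accepts either a :class:`ChoiceData` or a multi-session trial table.
    Chains run sequentially with seeds derived from ``sampler.seed``; results
    are deterministic given the seed.  A divergent-transition fraction above
    10% is flagged with a warning in the diagnostics (never silently).
    """
    if isinstance(data, pd.DataFrame):
        data = ChoiceData.from_trials(data)
    cfg = NutsConfig(n_warmup=sampler.warmup, n_draws=sampler.draws,
                     target_accept=sampler.target_accept,
                     max_treedepth=sampler.max_treedepth)

    def lpg(theta):
        return log_density_and_grad(theta, data, prior)

    ss = np.random.SeedSequence(sampler.seed)
    chain_seeds = ss.spawn(sampler.chains)
    all_draws = np.empty((sampler.chains, sampler.draws,
                          n_params(data.n_sessions)))
    total_div = 0
    step_sizes = []
    for c, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        theta0 = initial_point_from_data(data, prior, rng=rng, jitter=0.1)
        res = sample_nuts(lpg, theta0, rng, cfg)
        all_draws[c] = res.draws
        total_div += res.divergences
        step_sizes.append(res.step_size)

    diag = {
        "divergences": int(total_div),
        "divergence_fraction": total_div / (sampler.chains * sampler.draws),
        "step_sizes": step_sizes,
    }
    diag.update(_scalar_diagnostics(all_draws, data.n_sessions))
    if diag["divergence_fraction"] > 0.10:
        diag["divergence_warning"] = True
        warnings.warn(
            f"{diag['divergence_fraction']:.0%} divergent transitions; "
            "posterior may be unreliable", RuntimeWarning)
    else:
        diag["divergence_warning"] = False
    return PosteriorDraws(theta=all_draws, n_sessions=data.n_sessions,
                          diagnostics=diag)


@dataclass
class WeightTrajectory:
    """Per-session posterior summaries of the four choice weights.

    ``table`` has one row per (session, weight) with posterior mean and
    central 95% interval; ``alpha_mean`` / ``pi_mean`` are posterior means of
    the shared shape parameters.
    """

    table: pd.DataFrame
    alpha_mean: float
    pi_mean: float

    def weight_means(self, name: str) -> np.ndarray:
        sub = self.table[self.table["weight"] == name].sort_values("session")
        return sub["mean"].to_numpy()


def summarize_weights(draws: PosteriorDraws) -> WeightTrajectory:
    """Posterior mean and central 95% interval per session and weight."""
    beta = draws.beta  # (n, D, K)
    mean = beta.mean(axis=0)
    lo = np.quantile(beta, 0.025, axis=0)
    hi = np.quantile(beta, 0.975, axis=0)
    rows = []
    for d in range(draws.n_sessions):
        for k, name in enumerate(WEIGHT_NAMES):
            rows.append({"session": d + 1, "weight": name,
                         "mean": mean[d, k], "lo95": lo[d, k],
                         "hi95": hi[d, k]})
    return WeightTrajectory(table=pd.DataFrame(rows),
                            alpha_mean=float(draws.alpha.mean()),
                            pi_mean=float(draws.pi.mean()))


def predict_psychometric(weights: np.ndarray, alpha: float,
                         signed_contrasts: np.ndarray,
                         history: float = 0.0) -> np.ndarray:
    """Choice probability p(right) as a function of signed contrast.

    Positive contrasts are rightward stimuli, negative leftward; ``weights``
    is one session's ``[bias, right_stim, left_stim, history]`` vector and
    ``history`` the value of the choice-history regressor (0 by default).
    """
    sc = np.asarray(signed_contrasts, dtype=float)
    x = transform_contrast(np.abs(sc), alpha)
    lin = (weights[0]
           + np.where(sc > 0, weights[1] * x, 0.0)
           - np.where(sc < 0, weights[2] * x, 0.0)
           + weights[3] * history)
    return expit(lin)
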