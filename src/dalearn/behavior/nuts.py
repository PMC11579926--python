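"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained implementation of the dynamic-trajectory Hamiltonian Monte
Carlo variant with slice sampling over the trajectory (Hoffman & Gelman's
NUTS, algorithm 6) driven by a user-supplied ``logp_and_grad`` callable.
Warmup follows the usual three-phase schedule: a fast start buffer, a series
of doubling windows in which the diagonal metric is re-estimated from the
warmup draws, and a fast terminal buffer for step-size refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsConfig", "NutsResult", "sample_nuts"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass(frozen=True)
class NutsConfig:
    n_warmup: int = 500
    n_draws: int = 500
    target_accept: float = 0.9
    max_treedepth: int = 10
    init_buffer: int = 75
    term_buffer: int = 50
    base_window: int = 25


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim)
    logp: np.ndarray  # (n_draws,)
    divergences: int
    step_size: float
    inv_mass: np.ndarray
    accept_rate: float
    treedepths: np.ndarray


class _Tree:
    __slots__ = ("theta_m", "r_m", "g_m", "theta_p", "r_p", "g_p",
                 "theta_prop", "logp_prop", "n", "stop", "alpha", "n_alpha",
                 "diverged")


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp1, grad1


def _kinetic(r, inv_mass):
    return 0.5 * float(np.dot(r, inv_mass * r))


def _find_reasonable_eps(logp_grad, theta, rng, inv_mass):
    eps = 1.0
    logp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r, inv_mass)
    t1, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(r1, inv_mass)
    d = h1 - h0
    if not np.isfinite(d):
        d = -np.inf
    direction = 1.0 if d > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        t1, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(r1, inv_mass)
        d = h1 - h0
        if not np.isfinite(d):
            d = -np.inf
        if direction * d <= direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_grad, theta, r, grad, log_u, v, depth, eps, h0,
                inv_mass, rng):
    tree = _Tree()
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(logp_grad, theta, r, grad,
                                             v * eps, inv_mass)
        h1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        tree.theta_m = tree.theta_p = theta1
        tree.r_m = tree.r_p = r1
        tree.g_m = tree.g_p = grad1
        tree.theta_prop = theta1
        tree.logp_prop = logp1
        tree.n = 1 if log_u <= h1 else 0
        tree.diverged = log_u > h1 + _MAX_DELTA_H
        tree.stop = tree.diverged
        tree.alpha = min(1.0, float(np.exp(min(0.0, h1 - h0))))
        tree.n_alpha = 1
        return tree
    left = _build_tree(logp_grad, theta, r, grad, log_u, v, depth - 1, eps,
                       h0, inv_mass, rng)
    tree = left
    if not tree.stop:
        if v == -1:
            sub = _build_tree(logp_grad, tree.theta_m, tree.r_m, tree.g_m,
                              log_u, v, depth - 1, eps, h0, inv_mass, rng)
            tree.theta_m, tree.r_m, tree.g_m = sub.theta_m, sub.r_m, sub.g_m
        else:
            sub = _build_tree(logp_grad, tree.theta_p, tree.r_p, tree.g_p,
                              log_u, v, depth - 1, eps, h0, inv_mass, rng)
            tree.theta_p, tree.r_p, tree.g_p = sub.theta_p, sub.r_p, sub.g_p
        total = tree.n + sub.n
        if sub.n and rng.uniform() < sub.n / total:
            tree.theta_prop = sub.theta_prop
            tree.logp_prop = sub.logp_prop
        tree.alpha += sub.alpha
        tree.n_alpha += sub.n_alpha
        tree.n = total
        tree.diverged = tree.diverged or sub.diverged
        tree.stop = sub.stop or _uturn(tree, inv_mass)
    return tree


def _uturn(tree, inv_mass):
    dtheta = tree.theta_p - tree.theta_m
    return (float(np.dot(dtheta, inv_mass * tree.r_m)) < 0.0
            or float(np.dot(dtheta, inv_mass * tree.r_p)) < 0.0)


def sample_nuts(logp_grad: Callable, theta0: np.ndarray, rng: np.random.Generator,
                config: NutsConfig = NutsConfig()) -> NutsResult:
    """Run one chain of adaptive NUTS from ``theta0``."""
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_eps(logp_grad, theta, rng, inv_mass)
    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    cfg = config
    n_total = cfg.n_warmup + cfg.n_draws
    draws = np.empty((cfg.n_draws, dim))
    logps = np.empty(cfg.n_draws)
    depths = np.empty(cfg.n_draws, dtype=np.intp)
    divergences = 0
    accepts = []

    # slow-window schedule for mass adaptation
    windows = []
    if cfg.n_warmup >= cfg.init_buffer + cfg.term_buffer + cfg.base_window:
        start = cfg.init_buffer
        size = cfg.base_window
        while start + size < cfg.n_warmup - cfg.term_buffer:
            end = start + size
            if start + 3 * size >= cfg.n_warmup - cfg.term_buffer:
                end = cfg.n_warmup - cfg.term_buffer
            windows.append((start, end))
            start, size = end, size * 2
    window_samples: list[np.ndarray] = []
    warm_adapt_count = 0

    for it in range(n_total):
        warming = it < cfg.n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(r0, inv_mass)
        log_u = h0 + np.log(rng.uniform())
        tree = _Tree()
        tree.theta_m = tree.theta_p = theta
        tree.r_m = tree.r_p = r0
        g0 = grad
        tree.g_m = tree.g_p = g0
        tree.theta_prop, tree.logp_prop = theta, logp
        tree.n, tree.stop, tree.diverged = 1, False, False
        depth = 0
        sum_alpha, sum_n_alpha = 0.0, 0
        diverged = False
        while not tree.stop and depth < cfg.max_treedepth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                sub = _build_tree(logp_grad, tree.theta_m, tree.r_m, tree.g_m,
                                  log_u, v, depth, eps, h0, inv_mass, rng)
                tree.theta_m, tree.r_m, tree.g_m = sub.theta_m, sub.r_m, sub.g_m
            else:
                sub = _build_tree(logp_grad, tree.theta_p, tree.r_p, tree.g_p,
                                  log_u, v, depth, eps, h0, inv_mass, rng)
                tree.theta_p, tree.r_p, tree.g_p = sub.theta_p, sub.r_p, sub.g_p
            sum_alpha += sub.alpha
            sum_n_alpha += sub.n_alpha
            if not sub.stop and sub.n and rng.uniform() < min(1.0, sub.n / tree.n):
                tree.theta_prop = sub.theta_prop
                tree.logp_prop = sub.logp_prop
            tree.n += sub.n
            diverged = diverged or sub.diverged
            if sub.stop or _uturn(tree, inv_mass):
                break
            depth += 1
        if diverged and not warming:
            divergences += 1
        theta = tree.theta_prop
        logp = tree.logp_prop
        _, grad = logp_grad(theta)
        accept_stat = sum_alpha / max(sum_n_alpha, 1)

        if warming:
            # dual averaging
            warm_adapt_count += 1
            frac = 1.0 / (warm_adapt_count + t0_da)
            h_bar = (1.0 - frac) * h_bar + frac * (cfg.target_accept - accept_stat)
            log_eps = mu_da - np.sqrt(warm_adapt_count) / gamma_da * h_bar
            w = warm_adapt_count ** (-kappa_da)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            for (ws, we) in windows:
                if ws <= it < we:
                    window_samples.append(theta.copy())
                    if it == we - 1:
                        S = np.asarray(window_samples)
                        n = S.shape[0]
                        var = S.var(axis=0, ddof=1) if n > 1 else np.ones(dim)
                        # Stan-style shrink toward unit metric
                        var = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                        inv_mass = np.maximum(var, 1e-10)
                        window_samples = []
                        # restart step-size adaptation for the new metric
                        eps = _find_reasonable_eps(logp_grad, theta, rng,
                                                   inv_mass)
                        mu_da = np.log(10.0 * eps)
                        log_eps_bar, h_bar, warm_adapt_count = 0.0, 0.0, 0
                    break
        else:
            i = it - cfg.n_warmup
            draws[i] = theta
            logps[i] = logp
            depths[i] = depth
            accepts.append(accept_stat)
        if it == cfg.n_warmup - 1:
            eps = float(np.exp(log_eps_bar)) if warm_adapt_count else eps

    return NutsResult(draws=draws, logp=logps, divergences=divergences,
                      step_size=eps, inv_mass=inv_mass,
                      accept_rate=float(np.mean(accepts)) if accepts else np.nan,
                      treedepths=depths)
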