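"""Adaptive Hamiltonian Monte Carlo (No-U-Turn sampler).

A self-contained NUTS implementation over an arbitrary differentiable log
density, used as the reference backend for every model in the package.  The
target supplies ``logp_grad(theta) -> (float, ndarray)``; the sampler
handles leapfrog integration, the no-U-turn termination criterion (slice
variant), dual-averaging step-size adaptation toward a target acceptance
statistic, and diagonal mass-matrix estimation during warmup.

Models are parameterized on the unconstrained scale (log standard
deviations, non-centered random effects, stick-anchored simplexes), so a
diagonal metric is adequate for the posteriors fitted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "SamplerDiagnostics"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class SamplerDiagnostics:
    step_size: np.ndarray  # per chain
    n_divergent: np.ndarray  # per chain
    mean_accept: np.ndarray  # per chain
    mean_treedepth: np.ndarray  # per chain


class _Tree:
    __slots__ = ("theta_m", "r_m", "g_m", "theta_p", "r_p", "g_p", "theta_prop", "g_prop",
                 "logp_prop", "n", "stop", "alpha", "n_alpha", "diverged")


def _leapfrog(logp_grad, theta, r, grad, eps, minv):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * minv * r1
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, grad1, logp1


def _build_tree(logp_grad, theta, r, grad, logu, v, depth, eps, minv, h0, rng):
    t = _Tree()
    if depth == 0:
        theta1, r1, grad1, logp1 = _leapfrog(logp_grad, theta, r, grad, v * eps, minv)
        h1 = logp1 - 0.5 * float(np.sum(minv * r1 * r1))
        t.diverged = not np.isfinite(h1) or (logu - h1) > _MAX_DELTA_H
        t.n = 0 if (t.diverged or logu > h1) else 1
        t.stop = t.diverged
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.r_m = t.r_p = r1
        t.g_m = t.g_p = t.g_prop = grad1
        t.logp_prop = logp1
        t.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        return t
    # recursion: build left and right half-trees
    t = _build_tree(logp_grad, theta, r, grad, logu, v, depth - 1, eps, minv, h0, rng)
    if not t.stop:
        if v == -1:
            t2 = _build_tree(logp_grad, t.theta_m, t.r_m, t.g_m, logu, v, depth - 1, eps, minv, h0, rng)
            t.theta_m, t.r_m, t.g_m = t2.theta_m, t2.r_m, t2.g_m
        else:
            t2 = _build_tree(logp_grad, t.theta_p, t.r_p, t.g_p, logu, v, depth - 1, eps, minv, h0, rng)
            t.theta_p, t.r_p, t.g_p = t2.theta_p, t2.r_p, t2.g_p
        if t2.n > 0 and rng.random() < t2.n / max(t.n + t2.n, 1):
            t.theta_prop, t.g_prop, t.logp_prop = t2.theta_prop, t2.g_prop, t2.logp_prop
        t.n += t2.n
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        dtheta = t.theta_p - t.theta_m
        t.stop = (
            t2.stop
            or (dtheta @ (minv * t.r_m)) < 0
            or (dtheta @ (minv * t.r_p)) < 0
        )
        t.diverged = t.diverged or t2.diverged
    return t


def _find_initial_step(logp_grad, theta, grad, logp, minv, rng):
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(minv)
    h0 = logp - 0.5 * float(np.sum(minv * r * r))
    _, r1, _, logp1 = _leapfrog(logp_grad, theta, r, grad, eps, minv)
    h1 = logp1 - 0.5 * float(np.sum(minv * r1 * r1))
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        _, r1, _, logp1 = _leapfrog(logp_grad, theta, r, grad, eps, minv)
        h1 = logp1 - 0.5 * float(np.sum(minv * r1 * r1))
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * np.log(0.5):
            break
    return eps


def _nuts_chain(logp_grad, init, n_warmup, n_draws, rng, target_accept, max_treedepth):
    dim = init.size
    theta = init.astype(float).copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")
    minv = np.ones(dim)

    eps = _find_initial_step(logp_grad, theta, grad, logp, minv, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # warmup phases: step-size only / variance accumulation / step-size only
    phase_b_lo = int(0.15 * n_warmup)
    phase_b_hi = int(0.75 * n_warmup)
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((n_draws, dim))
    n_div = 0
    accept_sum = 0.0
    depth_sum = 0
    total = n_warmup + n_draws

    for it in range(total):
        r0 = rng.standard_normal(dim) / np.sqrt(minv)
        h0 = logp - 0.5 * float(np.sum(minv * r0 * r0))
        logu = h0 + np.log(rng.random())
        theta_m = theta_p = theta
        r_m = r_p = r0
        g_m = g_p = grad
        prop_theta, prop_grad, prop_logp = theta, grad, logp
        n_kept = 1
        depth = 0
        diverged = False
        while depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                t = _build_tree(logp_grad, theta_m, r_m, g_m, logu, v, depth, eps, minv, h0, rng)
                theta_m, r_m, g_m = t.theta_m, t.r_m, t.g_m
            else:
                t = _build_tree(logp_grad, theta_p, r_p, g_p, logu, v, depth, eps, minv, h0, rng)
                theta_p, r_p, g_p = t.theta_p, t.r_p, t.g_p
            if not t.stop and t.n > 0 and rng.random() < t.n / n_kept:
                prop_theta, prop_grad, prop_logp = t.theta_prop, t.g_prop, t.logp_prop
            n_kept += t.n
            diverged = diverged or t.diverged
            dtheta = theta_p - theta_m
            if t.stop or (dtheta @ (minv * r_m)) < 0 or (dtheta @ (minv * r_p)) < 0:
                break
            depth += 1
        theta, grad, logp = prop_theta, prop_grad, prop_logp
        alpha_stat = t.alpha / max(t.n_alpha, 1)

        if it < n_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if phase_b_lo <= it < phase_b_hi:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
            if it == phase_b_hi - 1 and welford_n > 4:
                var = welford_m2 / (welford_n - 1)
                minv = (welford_n / (welford_n + 5.0)) * var + (5.0 / (welford_n + 5.0))
                minv = np.clip(minv, 1e-8, 1e8)
                # restart step-size adaptation around the current value
                eps = _find_initial_step(logp_grad, theta, grad, logp, minv, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            j = it - n_warmup
            draws[j] = theta
            n_div += int(diverged)
            accept_sum += alpha_stat
            depth_sum += depth + 1
    return draws, eps, n_div, accept_sum / max(n_draws, 1), depth_sum / max(n_draws, 1)


def sample_nuts(
    logp_grad,
    init: np.ndarray,
    n_warmup: int = 500,
    n_draws: int = 500,
    n_chains: int = 4,
    seed: int | np.random.SeedSequence = 0,
    target_accept: float = 0.9,
    max_treedepth: int = 8,
    init_jitter: float = 0.5,
) -> tuple[np.ndarray, SamplerDiagnostics]:
    """Sample ``n_chains`` NUTS chains; returns draws (chain, draw, dim).

    Chains are seeded independently from ``seed`` and start from ``init``
    perturbed by uniform jitter, mimicking the common dispersed
    initialization so the split-chain convergence statistic is meaningful.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(n_chains)
    dim = init.size
    all_draws = np.empty((n_chains, n_draws, dim))
    eps = np.empty(n_chains)
    ndiv = np.empty(n_chains, dtype=int)
    macc = np.empty(n_chains)
    mdep = np.empty(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(child[c])
        start = init + init_jitter * rng.uniform(-1, 1, size=dim)
        with np.errstate(over="ignore", invalid="ignore"):
            # rejected trajectories may overflow the kinetic energy; the
            # resulting non-finite Hamiltonian is handled as a divergence
            d, e, nd, ma, md = _nuts_chain(
                logp_grad, start, n_warmup, n_draws, rng, target_accept, max_treedepth
            )
        all_draws[c] = d
        eps[c], ndiv[c], macc[c], mdep[c] = e, nd, ma, md
    return all_draws, SamplerDiagnostics(eps, ndiv, macc, mdep)
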