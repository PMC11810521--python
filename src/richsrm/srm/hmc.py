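"""Hamiltonian Monte Carlo with dual-averaging step-size and diagonal mass
adaptation.

A deliberately compact, dependency-free sampler for smooth, mostly-Gaussian
posteriors such as the non-centred SRM.  Trajectories use a fixed target
length with jittered leapfrog counts (to break periodicities); warmup
adapts the step size to a target acceptance statistic (Nesterov dual
averaging) and, three-quarters of the way through, replaces the identity
mass matrix with regularised sample variances of the warmup draws.

Divergent transitions (energy error > 1000) are rejected and counted.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclasses.dataclass
class ChainResult:
    draws: np.ndarray  # (samples, dim)
    accept_rate: float
    divergences: int
    step_size: float
    n_leapfrog: int


def _leapfrog(logp_grad: LogpGrad, x, p, grad, eps, inv_mass, n_steps):
    x = x.copy()
    p = p.copy()
    logp = None
    # diverging trajectories overflow legitimately; non-finite states are
    # detected below and returned as an infinite energy error
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(n_steps):
            p = p + 0.5 * eps * grad
            x = x + eps * inv_mass * p
            logp, grad = logp_grad(x)
            if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
                return x, p, -np.inf, grad
            p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _find_reasonable_epsilon(logp_grad, x, inv_mass, rng) -> float:
    eps = 0.1
    logp0, grad0 = logp_grad(x)
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * float(p0 * inv_mass @ p0)
    x1, p1, logp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps, inv_mass, 1)
    h1 = logp1 - 0.5 * float(p1 * inv_mass @ p1)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(50):
            eps *= 2.0 ** direction
            x1, p1, logp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps, inv_mass, 1)
            h1 = (
                logp1 - 0.5 * float(p1 * inv_mass @ p1)
                if np.isfinite(logp1)
                else -np.inf
            )
            if direction * (h1 - h0) < direction * np.log(0.5):
                break
    return float(np.clip(eps, 1e-6, 10.0))


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_leapfrog: int = 48,
    trajectory_length: float = 1.5,
) -> ChainResult:
    dim = x0.size
    x = np.asarray(x0, dtype=float).copy()
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("non-finite log-probability at the initial point")
    inv_mass = np.ones(dim)

    eps = _find_reasonable_epsilon(logp_grad, x, inv_mass, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # expanding mass-adaptation windows: re-estimate the diagonal mass at
    # each boundary so the step size can grow early in warmup
    mass_window_start = max(1, int(0.15 * n_warmup))
    boundaries = sorted(
        {
            max(mass_window_start + 10, int(f * n_warmup))
            for f in (0.3, 0.5, 0.75)
        }
    )
    window: list[np.ndarray] = []

    draws = np.empty((n_samples, dim))
    accepts = 0
    divergences = 0
    total_iters = n_warmup + n_samples
    n_leapfrog_base = 1

    for it in range(total_iters):
        warming = it < n_warmup
        n_leapfrog_base = int(np.clip(round(trajectory_length / eps), 1, max_leapfrog))
        lo = max(1, int(np.ceil(0.67 * n_leapfrog_base)))
        n_steps = int(rng.integers(lo, n_leapfrog_base + 1))

        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * float((p0 * p0 * inv_mass).sum())
        x1, p1, logp1, grad1 = _leapfrog(logp_grad, x, p0, grad, eps, inv_mass, n_steps)
        if np.isfinite(logp1):
            # diverging trajectories legitimately overflow the kinetic term;
            # the infinite energy is caught by the delta checks below
            with np.errstate(over="ignore"):
                h1 = logp1 - 0.5 * float((p1 * p1 * inv_mass).sum())
            delta = h1 - h0
        else:
            delta = -np.inf
        if delta < -1000.0 or not np.isfinite(delta):
            alpha = 0.0
            if not warming:  # warmup blowups are part of adaptation
                divergences += 1
        else:
            alpha = min(1.0, float(np.exp(min(delta, 0.0))))
            if np.log(rng.uniform()) < delta:
                x, logp, grad = x1, logp1, grad1
                if not warming:
                    accepts += 1

        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= mass_window_start:
                window.append(x.copy())
            if it + 1 in boundaries and len(window) >= 10:
                w = np.asarray(window)
                var = w.var(axis=0, ddof=1)
                nw = len(window)
                # Stan-style regularisation toward unit scale
                inv_mass = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                eps = _find_reasonable_epsilon(logp_grad, x, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
                window = []
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if adapt_count else eps
        else:
            draws[it - n_warmup] = x

    return ChainResult(
        draws=draws,
        accept_rate=accepts / max(1, n_samples),
        divergences=divergences,
        step_size=eps,
        n_leapfrog=n_leapfrog_base,
    )


def sample(
    logp_grad: LogpGrad,
    init: np.ndarray | Callable[[np.random.Generator], np.ndarray],
    chains: int,
    n_warmup: int,
    n_samples: int,
    seed: int,
    **kwargs,
) -> list[ChainResult]:
    """Run ``chains`` independent HMC chains (sequentially, reproducibly)."""
    seqs = np.random.SeedSequence(seed).spawn(chains)
    results = []
    for chain_seq in seqs:
        rng = np.random.default_rng(chain_seq)
        x0 = init(rng) if callable(init) else np.asarray(init, dtype=float)
        results.append(
            sample_chain(logp_grad, x0, n_warmup, n_samples, rng, **kwargs)
        )
    return results
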