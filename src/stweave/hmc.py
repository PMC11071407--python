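"""Adaptive Hamiltonian Monte Carlo on unconstrained parameter vectors.

A compact gradient-based sampler in the style of Stan's adaptive HMC: dual
averaging of the leapfrog step size toward a target acceptance rate during
warmup, a diagonal mass matrix estimated from warmup draws, and trajectory
lengths jittered uniformly up to a maximum to avoid periodic behavior.
All chains run vectorized in one numpy batch; per-chain step sizes and
accept/reject decisions are independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray          # (n_chains, n_samples, dim)
    accept_rate: np.ndarray    # per chain
    step_size: np.ndarray      # per chain, post-adaptation
    n_divergent: int


class _DualAveraging:
    """Nesterov dual averaging of log step size (per chain)."""

    def __init__(self, eps0: np.ndarray, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.h_bar = np.zeros_like(eps0)
        self.log_eps_bar = np.zeros_like(eps0)
        self.t = 0

    def update(self, accept_prob: np.ndarray) -> np.ndarray:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return np.exp(log_eps)

    @property
    def adapted(self) -> np.ndarray:
        return np.exp(self.log_eps_bar)


def _leapfrog(logp_grad: LogpGrad, q, p, grad, eps, minv, n_steps):
    eps = eps[:, None]
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * minv * p
        lp, grad = logp_grad(q)
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_leapfrog: int = 16,
    init_step: float = 0.1,
) -> HMCResult:
    """Run vectorized adaptive HMC chains.

    ``logp_grad`` maps a (n_chains, dim) batch of positions to per-chain log
    densities and gradients.  Warmup splits in two: the first half adapts the
    step size under a unit mass matrix, the second half re-adapts it under a
    diagonal mass estimated from first-phase draws.  Sampling then runs at
    the averaged step size.
    """
    q = np.array(x0, dtype=float)
    n_chains, dim = q.shape
    # transient excursions may overflow exp(); such proposals are rejected
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _sample_loop(logp_grad, q, n_warmup, n_samples, rng,
                            target_accept, max_leapfrog, init_step)


def _sample_loop(logp_grad, q, n_warmup, n_samples, rng, target_accept, max_leapfrog, init_step):
    n_chains, dim = q.shape
    lp, grad = logp_grad(q)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial positions have non-finite log density")
    minv = np.ones((1, dim))
    eps = np.full(n_chains, init_step / max(dim, 1) ** 0.25)

    w1 = max(n_warmup // 2, 1)
    phase1_draws = np.empty((n_chains, w1, dim))
    draws = np.empty((n_chains, n_samples, dim))
    n_divergent = 0
    accepts = np.zeros(n_chains)
    da = _DualAveraging(eps, target=target_accept)

    total = n_warmup + n_samples
    for it in range(total):
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        p = rng.standard_normal((n_chains, dim)) / np.sqrt(minv)
        h0 = -lp + 0.5 * np.sum(p * p * minv, axis=1)
        q_new, p_new, lp_new, grad_new = _leapfrog(logp_grad, q, p, grad, eps, minv, n_steps)
        h1 = -lp_new + 0.5 * np.sum(p_new * p_new * minv, axis=1)
        delta = h0 - h1
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        accept_prob = np.exp(np.minimum(delta, 0.0))
        if it >= n_warmup:
            n_divergent += int(np.sum(delta < -1000.0))
        u = rng.uniform(size=n_chains)
        acc = u < accept_prob
        q = np.where(acc[:, None], q_new, q)
        lp = np.where(acc, lp_new, lp)
        grad = np.where(acc[:, None], grad_new, grad)

        if it < n_warmup:
            eps = da.update(accept_prob)
            if it < w1:
                phase1_draws[:, it] = q
            if it == w1 - 1:
                # diagonal mass from the second half of phase-1 draws
                lo = w1 // 2
                var = phase1_draws[:, lo:w1].reshape(-1, dim).var(axis=0)
                minv = np.where(var > 1e-12, var, 1.0)[None, :]
                eps = np.full(n_chains, init_step / max(dim, 1) ** 0.25)
                da = _DualAveraging(eps, target=target_accept)
        else:
            if it == n_warmup:
                eps = da.adapted
            draws[:, it - n_warmup] = q
            accepts += acc

    return HMCResult(
        draws=draws,
        accept_rate=accepts / max(n_samples, 1),
        step_size=eps,
        n_divergent=n_divergent,
    )
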