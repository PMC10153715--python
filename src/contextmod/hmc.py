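"""Minimal Hamiltonian Monte Carlo with warmup adaptation.

A small, dependency-free sampler sufficient for the hierarchical psychometric
model: static-trajectory HMC with

* dual-averaging step-size adaptation toward a target acceptance rate
  (Nesterov-style, the scheme popularized by NUTS implementations),
* diagonal mass-matrix estimation from a middle warmup window,
* jittered leapfrog path lengths to avoid resonances,
* divergence accounting (energy error > 1000 discards the trajectory).

The model supplies a fused ``logp_and_grad(theta) -> (float, ndarray)``; the
analytic gradient keeps a ~1000-dimensional posterior tractable in numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DIVERGENCE_ENERGY = 1000.0


@dataclass
class HMCResult:
    draws: np.ndarray          # (chains, kept, dim)
    accept_rate: np.ndarray    # (chains,)
    divergences: int
    step_sizes: np.ndarray     # (chains,)


class _DualAveraging:
    """Step-size adaptation toward a target acceptance statistic."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _leapfrog(logp_and_grad, theta, p, grad, eps, n_steps, inv_mass):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        theta = theta + eps * inv_mass * p
        logp, grad = logp_and_grad(theta)
        if not np.isfinite(logp):
            return theta, p, logp, grad
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return theta, p, logp, grad


def sample_hmc(logp_and_grad, init: np.ndarray, *, n_chains: int,
               n_iter: int, n_warmup: int, seed: int,
               n_leapfrog: int = 24, target_accept: float = 0.8,
               init_jitter: float = 0.05) -> HMCResult:
    """Run ``n_chains`` independent chains, keeping ``n_iter - n_warmup`` draws each.

    Warmup: the first 15 % adapts the step size under unit mass, the middle
    75 % additionally accumulates draws for a (regularized) diagonal mass
    estimate, and the final 10 % re-adapts the step size under that metric.
    """
    dim = init.size
    kept = n_iter - n_warmup
    if kept <= 0:
        raise ValueError("n_iter must exceed n_warmup")
    draws = np.empty((n_chains, kept, dim))
    accept = np.zeros(n_chains)
    step_sizes = np.zeros(n_chains)
    divergences = 0

    # Stan-style warmup layout: an initial step-size buffer, expanding
    # "memoryless" mass-estimation windows, and a terminal step-size buffer
    buf1 = max(1, int(0.15 * n_warmup))
    buf2 = max(1, int(0.10 * n_warmup))
    window_ends = []
    start, width = buf1, max(10, int(0.05 * n_warmup))
    while start < n_warmup - buf2:
        end = min(start + width, n_warmup - buf2)
        if (n_warmup - buf2) - end < width:   # absorb the remainder
            end = n_warmup - buf2
        window_ends.append(end)
        start, width = end, width * 2
    window_end_set = set(window_ends)

    for chain in range(n_chains):
        rng = np.random.default_rng(seed + 1000 * chain)
        theta = init + init_jitter * rng.standard_normal(dim)
        logp, grad = logp_and_grad(theta)
        inv_mass = np.ones(dim)
        da = _DualAveraging(0.1 / dim ** 0.25, target=target_accept)
        eps = np.exp(da.log_eps)
        window_sum = np.zeros(dim)
        window_sq = np.zeros(dim)
        window_n = 0
        n_accept = 0.0

        for it in range(n_iter):
            p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
            n_steps = int(rng.integers(max(1, int(0.8 * n_leapfrog)),
                                       n_leapfrog + 1))
            h0 = -logp + 0.5 * np.sum(p0 * p0 * inv_mass)
            theta_new, p_new, logp_new, grad_new = _leapfrog(
                logp_and_grad, theta, p0, grad, eps, n_steps, inv_mass)
            if np.isfinite(logp_new):
                h1 = -logp_new + 0.5 * np.sum(p_new * p_new * inv_mass)
                delta = h0 - h1
                accept_prob = min(1.0, np.exp(min(0.0, delta)))
                diverged = -delta > DIVERGENCE_ENERGY
            else:
                accept_prob, diverged = 0.0, True
            if diverged and it >= n_warmup:
                divergences += 1
            if not diverged and rng.random() < accept_prob:
                theta, logp, grad = theta_new, logp_new, grad_new

            if it < n_warmup:
                eps = da.update(accept_prob)
                in_window = buf1 <= it < n_warmup - buf2
                if in_window:
                    window_sum += theta
                    window_sq += theta * theta
                    window_n += 1
                if it + 1 in window_end_set:
                    if window_n > 10:
                        var = (window_sq / window_n
                               - (window_sum / window_n) ** 2)
                        # shrink toward unit variance for stability
                        var = (window_n * var + 5.0) / (window_n + 5.0)
                        inv_mass = np.maximum(var, 1e-8)
                        da = _DualAveraging(max(da.adapted, 1e-8),
                                            target=target_accept)
                        eps = np.exp(da.log_eps)
                    window_sum[:] = 0.0
                    window_sq[:] = 0.0
                    window_n = 0
                if it == n_warmup - 1:
                    eps = da.adapted
            else:
                draws[chain, it - n_warmup] = theta
                n_accept += accept_prob

        accept[chain] = n_accept / kept
        step_sizes[chain] = eps
    return HMCResult(draws=draws, accept_rate=accept,
                     divergences=divergences, step_sizes=step_sizes)
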