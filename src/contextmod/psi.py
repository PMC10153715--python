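"""Psi adaptive staircase for the contrast-detection simulation.

A discretized posterior over psychometric parameters (threshold alpha in
log10 contrast, slope beta in logit units per decade) is updated by Bayes'
rule after every trial; each stimulus is the lattice contrast minimizing the
expected posterior entropy over the two possible responses.

The staircase's internal model is the logistic with a fixed 0.5 guess rate
and no lapse — the same family the analysis stage fits — rather than the
Weibull sometimes used with this procedure:

    P(correct | x, alpha, beta) = 0.5 + 0.5 * logistic(beta * (x - alpha))

Entropy bookkeeping uses the decomposition
E[H] = sum_r p(r) H(posterior | r), with every term reduced to matrix-vector
products against precomputed likelihood tables, so stimulus selection over a
350-value lattice and a 61 x 25 parameter grid costs four small matvecs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy

from .design import DetectionDesign, contrast_pool
from .observers import ObserverParams, response_probability


@dataclass(frozen=True)
class PsiConfig:
    stimulus_lattice: np.ndarray = field(
        default_factory=lambda: contrast_pool())
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-3.0, 0.0, 61))
    beta_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.5, 32.0, 25))
    guess: float = 0.5
    n_trials: int = 40

    def __post_init__(self) -> None:
        for name in ("stimulus_lattice", "alpha_grid", "beta_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, g)
            if g.size == 0 or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be non-empty, strictly increasing")

    @property
    def n_grid(self) -> int:
        return self.alpha_grid.size * self.beta_grid.size


class _Tables:
    """Per-config likelihood tables shared by all staircases.

    L[i, g] = P(correct | stimulus i, grid cell g); plus L*log(L) and the
    failure-branch counterparts, enabling matvec-only entropy evaluation.
    """

    def __init__(self, config: PsiConfig) -> None:
        x = np.log10(config.stimulus_lattice)[:, None]
        alpha = np.repeat(config.alpha_grid, config.beta_grid.size)[None, :]
        beta = np.tile(config.beta_grid, config.alpha_grid.size)[None, :]
        L = config.guess + (1 - config.guess) * expit(beta * (x - alpha))
        self.success = L
        self.failure = 1.0 - L
        self.success_logl = xlogy(L, L)
        self.failure_logl = xlogy(1.0 - L, 1.0 - L)


_table_cache: dict[int, tuple[PsiConfig, _Tables]] = {}


def _tables(config: PsiConfig) -> _Tables:
    key = id(config)
    hit = _table_cache.get(key)
    if hit is None:
        hit = (config, _Tables(config))
        _table_cache[key] = hit
    return hit[1]


@dataclass
class PsiState:
    """Posterior mass over the (alpha, beta) grid plus the trial history."""

    config: PsiConfig
    posterior: np.ndarray                       # flat, alpha-major
    history: list[tuple[float, int]] = field(default_factory=list)

    def entropy(self) -> float:
        return float(-xlogy(self.posterior, self.posterior).sum())

    def posterior_mean_alpha(self) -> float:
        alpha = np.repeat(self.config.alpha_grid, self.config.beta_grid.size)
        return float(alpha @ self.posterior)

    def posterior_mean_beta(self) -> float:
        beta = np.tile(self.config.beta_grid, self.config.alpha_grid.size)
        return float(beta @ self.posterior)


def init_psi(config: PsiConfig) -> PsiState:
    """Uniform prior over the parameter grid, empty history."""
    k = config.n_grid
    return PsiState(config=config, posterior=np.full(k, 1.0 / k))


def expected_entropies(state: PsiState) -> np.ndarray:
    """Expected posterior entropy after presenting each lattice stimulus.

    For response r with predictive probability p_r = sum_g w_g L_rg, the
    conditional posterior is w L_r / p_r, whose entropy expands into sums of
    w L log L and w L log w, each a matvec against the cached tables.
    """
    t = _tables(state.config)
    w = state.posterior
    wlogw = xlogy(w, w)

    out = np.zeros(state.config.stimulus_lattice.size)
    for L, LlogL in ((t.success, t.success_logl), (t.failure, t.failure_logl)):
        p = L @ w                                   # predictive prob of branch
        s = LlogL @ w + L @ wlogw                   # sum w L log(w L)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 1e-300, xlogy(p, p) - s, 0.0)
        out += h                                    # p * H(post | r)
    return out


def select_stimulus(state: PsiState) -> int:
    """Lattice index minimizing expected posterior entropy (ties: lowest)."""
    return int(np.argmin(expected_entropies(state)))


def update_posterior(state: PsiState, stimulus, response: int) -> PsiState:
    """Bayes update after observing ``response`` (1 correct / 0 incorrect)."""
    if isinstance(stimulus, (int, np.integer)):
        idx = int(stimulus)
    else:
        idx = int(np.argmin(np.abs(state.config.stimulus_lattice - stimulus)))
        if not np.isclose(state.config.stimulus_lattice[idx], stimulus):
            raise ValueError(f"stimulus {stimulus} not in lattice")
    t = _tables(state.config)
    like = t.success[idx] if response else t.failure[idx]
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise FloatingPointError("posterior mass vanished in update")
    return PsiState(config=state.config, posterior=post / total,
                    history=state.history + [
                        (float(state.config.stimulus_lattice[idx]), int(response))])


def run_psi_session(obs: ObserverParams, config: PsiConfig, context: str,
                    n_staircases: int = 2, seed: int = 0,
                    block: int = 0) -> tuple[pd.DataFrame, list[PsiState]]:
    """One detection block: interleaved staircases against a synthetic observer.

    Staircases strictly alternate trials; each runs its own
    select -> simulate -> update loop.  Returns the trial records
    (response = 1 iff correct) and the final staircase states.
    """
    rng = np.random.default_rng(seed)
    states = [init_psi(config) for _ in range(n_staircases)]
    rows = []
    n_total = config.n_trials * n_staircases
    for trial in range(n_total):
        sc = trial % n_staircases
        idx = select_stimulus(states[sc])
        contrast = float(config.stimulus_lattice[idx])
        p = response_probability(obs, "Grating", context, np.log10(contrast))
        response = int(rng.random() < p)
        states[sc] = update_posterior(states[sc], idx, response)
        rows.append(dict(participant=obs.subject, task="Grating",
                         context=context, x_raw=contrast, response=response,
                         block=block, staircase=sc, trial_index=trial,
                         posterior_mean_alpha=states[sc].posterior_mean_alpha(),
                         posterior_mean_beta=states[sc].posterior_mean_beta()))
    return pd.DataFrame(rows), states


def pooled_posterior(states: list[PsiState]) -> np.ndarray:
    """Combine interleaved staircases' evidence into one posterior.

    Trials are conditionally independent given (alpha, beta) and all
    staircases start from the same uniform prior, so the joint posterior over
    the session is the normalized product of the per-staircase posteriors
    (the shared flat prior contributes only a constant).
    """
    if not states:
        raise ValueError("need at least one staircase state")
    logp = sum(np.log(np.maximum(s.posterior, 1e-300)) for s in states)
    w = np.exp(logp - logp.max())
    return w / w.sum()


def session_threshold(states: list[PsiState],
                      estimator: str = "map") -> float:
    """Session-level threshold (log10 contrast) from pooled staircases.

    The default "map" estimator takes the mode of the pooled alpha marginal:
    across simulated sessions it is the least biased of the three options
    (the posterior mean inherits a downward pull from occasional
    shallow-slope posterior excursions).  "mean" and "median" are available
    for comparison.
    """
    cfg = states[0].config
    w = pooled_posterior(states)
    marginal = w.reshape(cfg.alpha_grid.size, cfg.beta_grid.size).sum(axis=1)
    if estimator == "map":
        return float(cfg.alpha_grid[np.argmax(marginal)])
    if estimator == "mean":
        return float(marginal @ cfg.alpha_grid)
    if estimator == "median":
        return float(cfg.alpha_grid[np.searchsorted(np.cumsum(marginal), 0.5)])
    raise ValueError(f"unknown estimator {estimator!r}")


def run_detection_sessions(obs: ObserverParams, design: DetectionDesign,
                           config: PsiConfig | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Simulate the full 9-block detection task for one observer (720 trials)."""
    if config is None:
        config = PsiConfig(stimulus_lattice=design.contrast_pool)
    frames = []
    offset = 0
    for bi, blk in enumerate(design.blocks):
        records, _ = run_psi_session(obs, config, blk.context,
                                     n_staircases=len(blk.staircase_ids),
                                     seed=seed + bi, block=bi)
        records["trial_index"] += offset
        offset += len(records)
        frames.append(records)
    return pd.concat(frames, ignore_index=True)
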