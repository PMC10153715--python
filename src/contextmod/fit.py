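"""Hierarchical Bayesian psychometric model and threshold derivation.

The model pools both tasks into one Bernoulli GLMM with a guess-rate-aware
logit link:

    P(y = 1) = 0.5 * guess + (1 - 0.5 * guess) * logistic(eta)
    eta = x * task * condition + (x * task * condition || participant)

``x`` is the scaled local input strength (z-scored morph dissimilarity for
the eye tasks; z-scored log10 contrast for detection), ``guess`` is 1 for the
2-AFC detection task and 0 for eye matching.  Predictors are dummy-coded
(reference levels: task = UprightFace, condition = Isolated); random effects
are per-participant deviations on every fixed-effect term, mutually
uncorrelated ("||"), with Normal(0, 5) priors on the fixed weights and
LogNormal(0, 1) priors on the random-effect SDs.

Sampling is Hamiltonian Monte Carlo with analytic gradients on the
non-centered parameterization (see :mod:`contextmod.hmc`).  Per-cell
psychometric thresholds are derived draw-by-draw as -intercept/slope — the
50 % point of the logistic core, i.e. 75 % correct under a 0.5 guess rate —
then summarized by posterior mean and 95 % highest-density interval and
back-transformed to native units (morph % or Michelson contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .hmc import sample_hmc
from .observers import CONDITIONS, GUESS, TASKS

_P_FLOOR = 1e-12


@dataclass(frozen=True)
class InputScaler:
    """Invertible map from native input units to the scaled analysis axis."""

    log10: bool
    mean: float
    sd: float

    def transform(self, raw):
        v = np.log10(raw) if self.log10 else np.asarray(raw, dtype=float)
        return (v - self.mean) / self.sd

    def inverse(self, scaled):
        v = np.asarray(scaled, dtype=float) * self.sd + self.mean
        return 10.0 ** v if self.log10 else v


@dataclass
class ScaledDataset:
    """Trial table on the common scaled-input axis.

    Columns: participant, task, condition, x (scaled), y (0/1), guess.
    """

    frame: pd.DataFrame
    scalers: dict[str, InputScaler]


def scale_inputs(trials: pd.DataFrame) -> ScaledDataset:
    """Z-score local input strength per task (after log10 for detection).

    The trial-weighted scaling brings both tasks onto a common roughly
    -3..3 axis and is stored for exact inversion.
    """
    frame = trials.rename(columns={"context": "condition",
                                   "response": "y"}).copy()
    scalers: dict[str, InputScaler] = {}
    frame["x"] = 0.0
    frame["guess"] = frame["task"].map(GUESS)
    if frame["guess"].isna().any():
        bad = sorted(set(frame["task"]) - set(GUESS))
        raise ValueError(f"unknown task levels: {bad}")
    for task, sub in frame.groupby("task"):
        raw = sub["x_raw"].to_numpy(dtype=float)
        uses_log = bool(GUESS[task])
        if uses_log and (raw <= 0).any():
            raise ValueError("contrast values must be strictly positive")
        v = np.log10(raw) if uses_log else raw
        scaler = InputScaler(log10=uses_log, mean=float(v.mean()),
                             sd=float(v.std()))
        if scaler.sd == 0:
            raise ValueError(f"degenerate input values in task {task}")
        scalers[task] = scaler
        frame.loc[sub.index, "x"] = scaler.transform(raw)
    cols = ["participant", "task", "condition", "x", "y", "guess"]
    return ScaledDataset(frame=frame[cols], scalers=scalers)


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    iterations: int = 6000
    warmup: int = 3000
    seed: int = 1
    n_leapfrog: int = 24
    target_accept: float = 0.8
    prior_scale_fixed: float = 5.0     # Normal(0, scale) on fixed weights
    prior_sd_mu: float = 0.0           # LogNormal(mu, sigma) on RE SDs
    prior_sd_sigma: float = 1.0

    @property
    def retained_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)

    def to_json(self) -> str:
        import dataclasses
        import json
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def paper_profile(cls, seed: int = 1) -> "SamplerConfig":
        """Four chains of 6000 iterations, half warmup: 12000 retained draws."""
        return cls(chains=4, iterations=6000, warmup=3000, seed=seed)

    @classmethod
    def fast_profile(cls, seed: int = 1) -> "SamplerConfig":
        """Two chains x 600 retained draws; for CI and quick exploration."""
        return cls(chains=2, iterations=1000, warmup=400, seed=seed,
                   n_leapfrog=32)


def _term_labels(tasks, conditions) -> list[str]:
    """Names of the dummy-coded intercept-block terms, in column order."""
    labels = ["Intercept"]
    labels += [f"task[{t}]" for t in tasks[1:]]
    labels += [f"cond[{c}]" for c in conditions[1:]]
    labels += [f"task[{t}]:cond[{c}]"
               for t in tasks[1:] for c in conditions[1:]]
    return labels


def _dummy_map(n_tasks: int, n_conds: int) -> np.ndarray:
    """Map from dummy-coded coefficients to per-cell values.

    Row order: cells in (task-major, condition-minor) order; column order:
    [const, task dummies, condition dummies, task x condition dummies].
    """
    k = n_tasks * n_conds
    T = np.zeros((k, k))
    for ti in range(n_tasks):
        for ci in range(n_conds):
            row = T[ti * n_conds + ci]
            row[0] = 1.0
            if ti > 0:
                row[ti] = 1.0
            if ci > 0:
                row[n_tasks - 1 + ci] = 1.0
            if ti > 0 and ci > 0:
                row[n_tasks + n_conds - 2 + (ti - 1) * (n_conds - 1) + ci] = 1.0
    return T


@dataclass
class FitResult:
    """Posterior draws and bookkeeping for one fitted model."""

    beta: np.ndarray              # (chains, kept, 2k) fixed effects
    tau: np.ndarray               # (chains, kept, 2k) log random-effect SDs
    z_re: np.ndarray              # (chains, kept, S, 2k) standardized deviations
    participants: np.ndarray
    tasks: tuple[str, ...]
    conditions: tuple[str, ...]
    scalers: dict[str, InputScaler]
    config: SamplerConfig
    diagnostics: dict = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.tasks) * len(self.conditions)

    @property
    def retained_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("rhat_max", np.inf) < 1.05
                    and self.diagnostics.get("divergences", 1) == 0)

    def save_draws(self, path) -> None:
        """Write fixed-effect and random-effect-SD draws as columnar CSV.

        Columns are named after the dummy-coded terms (``b_``/``sd_``
        prefixes); one row per retained draw, chain-major.
        """
        labels = _term_labels(self.tasks, self.conditions)
        k = self.n_cells
        cols = {}
        beta = self.beta.reshape(-1, 2 * k)
        sd = np.exp(self.tau.reshape(-1, 2 * k))
        for j, lab in enumerate(labels):
            cols[f"b_{lab}"] = beta[:, j]
            cols[f"b_x:{lab}"] = beta[:, k + j]
        for j, lab in enumerate(labels):
            cols[f"sd_{lab}"] = sd[:, j]
            cols[f"sd_x:{lab}"] = sd[:, k + j]
        frame = pd.DataFrame(cols)
        frame.insert(0, "chain", np.repeat(np.arange(self.beta.shape[0]),
                                           self.beta.shape[1]))
        frame.to_csv(path, index=False)

    def cell_index(self, task: str, condition: str) -> int:
        return (self.tasks.index(task) * len(self.conditions)
                + self.conditions.index(condition))

    def dummy_map(self) -> np.ndarray:
        return _dummy_map(len(self.tasks), len(self.conditions))


def _model_arrays(data: ScaledDataset, tasks, conditions):
    df = data.frame
    s_codes = pd.Categorical(df["participant"]).codes
    participants = pd.Categorical(df["participant"]).categories.to_numpy()
    t_codes = pd.Categorical(df["task"], categories=tasks).codes
    c_codes = pd.Categorical(df["condition"], categories=conditions).codes
    if (t_codes < 0).any() or (c_codes < 0).any():
        raise ValueError("task/condition outside modeled factor levels")
    cell = t_codes * len(conditions) + c_codes
    idx = s_codes.astype(np.int64) * (len(tasks) * len(conditions)) + cell
    return (participants, s_codes, cell, idx,
            df["x"].to_numpy(float), df["y"].to_numpy(float),
            df["guess"].to_numpy(float))


def _make_logp(idx, cell, x, y, g, T, n_subj, cfg: SamplerConfig):
    k = T.shape[0]
    a = 0.5 * g
    b = 1.0 - 0.5 * g
    var_fixed = cfg.prior_scale_fixed ** 2
    n_cells = k

    def logp_and_grad(theta):
        beta = theta[:2 * k]
        tau = theta[2 * k:4 * k]
        z = theta[4 * k:].reshape(n_subj, 2 * k)
        sigma = np.exp(np.clip(tau, -20, 20))
        u = sigma * z
        acell = T @ beta[:k]
        bcell = T @ beta[k:]
        ucell = u[:, :k] @ T.T
        vcell = u[:, k:] @ T.T
        eta = (acell[cell] + bcell[cell] * x
               + ucell.reshape(-1)[idx] + vcell.reshape(-1)[idx] * x)
        s = expit(eta)
        p = np.clip(a + b * s, _P_FLOOR, 1 - _P_FLOOR)
        ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        tau_c = np.clip(tau, -20, 20)
        lp = (ll - 0.5 * np.sum(beta * beta) / var_fixed
              - 0.5 * np.sum((tau_c - cfg.prior_sd_mu) ** 2)
              / cfg.prior_sd_sigma ** 2
              - 0.5 * np.sum(z * z))

        deta = (y / p - (1 - y) / (1 - p)) * b * s * (1 - s)
        g1 = np.bincount(idx, weights=deta,
                         minlength=n_subj * n_cells).reshape(n_subj, n_cells)
        gx = np.bincount(idx, weights=deta * x,
                         minlength=n_subj * n_cells).reshape(n_subj, n_cells)
        dbeta = np.concatenate([g1.sum(0) @ T, gx.sum(0) @ T])
        dbeta -= beta / var_fixed
        du = np.concatenate([g1 @ T, gx @ T], axis=1)
        dz = du * sigma - z
        dtau = ((du * z).sum(0) * sigma
                - (tau_c - cfg.prior_sd_mu) / cfg.prior_sd_sigma ** 2)
        return lp, np.concatenate([dbeta, dtau, dz.reshape(-1)])

    return logp_and_grad


def fit_model(data: ScaledDataset,
              mcmc: SamplerConfig | None = None) -> FitResult:
    """Sample the hierarchical psychometric model.

    Diagnostics (split-R-hat, bulk ESS, divergences) are computed for every
    parameter; non-convergence is flagged in the result, never hidden.
    """
    import arviz as az

    mcmc = mcmc or SamplerConfig()
    df = data.frame
    tasks = tuple(t for t in TASKS if t in set(df["task"]))
    conditions = tuple(c for c in CONDITIONS if c in set(df["condition"]))
    participants, s_codes, cell, idx, x, y, g = _model_arrays(
        data, tasks, conditions)
    n_subj = participants.size
    if n_subj < 2:
        raise ValueError("need at least two participants")
    counts = df.groupby(["participant", "task", "condition"]).size()
    if len(counts) < n_subj * len(tasks) * len(conditions):
        raise ValueError("every participant must have trials in every cell")

    warns: list[str] = []
    rates = df.groupby(["participant", "task", "condition"])["y"].mean()
    degenerate = rates[(rates == 0) | (rates == 1)]
    for key in degenerate.index:
        msg = f"degenerate cell (all-same responses): {key}"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    k = len(tasks) * len(conditions)
    T = _dummy_map(len(tasks), len(conditions))
    logp_and_grad = _make_logp(idx, cell, x, y, g, T, n_subj, mcmc)
    dim = 4 * k + 2 * k * n_subj
    init = np.zeros(dim)
    init[2 * k:4 * k] = -1.0   # start RE SDs small-ish (sigma ~ 0.37)

    res = sample_hmc(logp_and_grad, init, n_chains=mcmc.chains,
                     n_iter=mcmc.iterations, n_warmup=mcmc.warmup,
                     seed=mcmc.seed, n_leapfrog=mcmc.n_leapfrog,
                     target_accept=mcmc.target_accept)

    beta = res.draws[:, :, :2 * k]
    tau = res.draws[:, :, 2 * k:4 * k]
    z_re = res.draws[:, :, 4 * k:].reshape(
        mcmc.chains, -1, n_subj, 2 * k)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={"beta": beta, "tau": tau,
                                        "z": res.draws[:, :, 4 * k:]})
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_max = float(max(rhat[v].max() for v in rhat.data_vars))
    ess_min = float(min(ess[v].min() for v in ess.data_vars))
    diagnostics = {
        "rhat_max": rhat_max,
        "ess_min": ess_min,
        "divergences": int(res.divergences),
        "accept_rate": res.accept_rate.tolist(),
        "step_sizes": res.step_sizes.tolist(),
        "rhat_beta": np.asarray(rhat["beta"]).tolist(),
    }
    fit = FitResult(beta=beta, tau=tau, z_re=z_re, participants=participants,
                    tasks=tasks, conditions=conditions, scalers=data.scalers,
                    config=mcmc, diagnostics=diagnostics, warnings_=warns)
    if rhat_max > 1.05 or res.divergences > 0:
        msg = (f"sampler convergence flagged: max R-hat {rhat_max:.3f}, "
               f"{res.divergences} divergences")
        fit.warnings_.append(msg)
        warnings.warn(msg, stacklevel=2)
    return fit


def _flat(a: np.ndarray) -> np.ndarray:
    return a.reshape(-1, *a.shape[2:])


def cell_coefficients(fit: FitResult, participant, task: str,
                      condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw (intercept, slope) for one participant x cell.

    Sums every fixed-effect and participant-deviation term active for the
    cell under the dummy coding; the reference cell reduces to the global
    intercept/slope plus that participant's deviation.
    """
    where = np.flatnonzero(fit.participants == participant)
    if not where.size:
        raise KeyError(f"unknown participant {participant!r}")
    s = int(where[0])
    k = fit.n_cells
    row = fit.dummy_map()[fit.cell_index(task, condition)]
    beta = _flat(fit.beta)
    u = np.exp(_flat(fit.tau)) * _flat(fit.z_re)[:, s, :]
    intercept = (beta[:, :k] + u[:, :k]) @ row
    slope = (beta[:, k:] + u[:, k:]) @ row
    return intercept, slope


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (unimodal HDI)."""
    x = np.sort(np.asarray(draws).ravel())
    n = x.size
    m = max(1, int(np.floor(prob * n)))
    widths = x[m:] - x[:n - m]
    if widths.size == 0:
        return float(x[0]), float(x[-1])
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def derive_thresholds(fit: FitResult, hdi_prob: float = 0.95,
                      slope_eps: float = 0.01) -> pd.DataFrame:
    """Per participant x task x condition threshold table.

    Thresholds are computed per posterior draw (-intercept/slope is nonlinear,
    so summarizing coefficients first would bias them), then summarized by
    posterior mean and HDI, and back-transformed to native units through the
    task's input scaler.  Cells where >= 1 % of slope draws fall within
    ``slope_eps`` of zero are flagged unstable.
    """
    k = fit.n_cells
    T = fit.dummy_map()
    beta = _flat(fit.beta)                    # (D, 2k)
    tau = np.exp(_flat(fit.tau))
    z = _flat(fit.z_re)                       # (D, S, 2k)
    u = tau[:, None, :] * z
    acell = beta[:, :k] @ T.T                 # (D, k)
    bcell = beta[:, k:] @ T.T
    ucell = u[:, :, :k] @ T.T                 # (D, S, k)
    vcell = u[:, :, k:] @ T.T
    intercept = acell[:, None, :] + ucell
    slope = bcell[:, None, :] + vcell
    thr = -intercept / slope

    rows = []
    for si, participant in enumerate(fit.participants):
        for ti, task in enumerate(fit.tasks):
            scaler = fit.scalers[task]
            for ci, cond in enumerate(fit.conditions):
                c = ti * len(fit.conditions) + ci
                draws = thr[:, si, c]
                lo, hi = hdi(draws, hdi_prob)
                mean = float(draws.mean())
                unstable = float(
                    (np.abs(slope[:, si, c]) < slope_eps).mean()) >= 0.01
                rows.append(dict(
                    participant=participant, task=task, condition=cond,
                    threshold=mean, hdi_lower=lo, hdi_upper=hi,
                    threshold_native=float(scaler.inverse(mean)),
                    native_lower=float(scaler.inverse(lo)),
                    native_upper=float(scaler.inverse(hi)),
                    unstable=unstable))
    return pd.DataFrame(rows)


@dataclass
class ConditionContrast:
    task: str
    condition_a: str
    condition_b: str
    posterior: np.ndarray      # per-draw group-level threshold difference
    mean: float
    hdi_lower: float
    hdi_upper: float
    excludes_zero: bool


def condition_contrasts(fit: FitResult, task: str, cond_a: str,
                        cond_b: str, hdi_prob: float = 0.95) -> ConditionContrast:
    """Group-level (fixed-effects-only) threshold difference cond_a - cond_b."""
    k = fit.n_cells
    T = fit.dummy_map()
    beta = _flat(fit.beta)
    diffs = []
    for cond in (cond_a, cond_b):
        row = T[fit.cell_index(task, cond)]
        thr = -(beta[:, :k] @ row) / (beta[:, k:] @ row)
        diffs.append(thr)
    posterior = diffs[0] - diffs[1]
    lo, hi = hdi(posterior, hdi_prob)
    return ConditionContrast(
        task=task, condition_a=cond_a, condition_b=cond_b,
        posterior=posterior, mean=float(posterior.mean()),
        hdi_lower=lo, hdi_upper=hi,
        excludes_zero=bool(lo > 0 or hi < 0))
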