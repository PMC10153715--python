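"""Synthetic observers: trial-level Bernoulli responders with known psychometrics.

Each observer carries, for every task x context cell, a logistic psychometric
function on that task's analysis axis:

* eye matching (UprightFace / InvertedFace): z-scored morph dissimilarity;
  "Different"-response probability = logistic(b0 + b1 x), guess rate 0.
* contrast detection (Grating): log10 Michelson contrast; probability correct
  = 0.5 + 0.5 * logistic(b0 + b1 x), guess rate 0.5 (2-AFC).

The population generator injects, over and above the components of the Same
threshold predictable from the Isolated and Different thresholds, a latent
per-subject "contextual-modulation magnitude" whose correlation across a
designated task pair is a configurable ground truth (``rho_magnitude``).
The two-step regression-of-regressions statistic targets exactly this latent
component, which makes it recoverable by construction.

No lapse parameter is modeled, deliberately mirroring the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import EyeMatchingDesign

TASKS = ("UprightFace", "InvertedFace", "Grating")
CONDITIONS = ("Isolated", "Different", "Same")
#: guess-rate indicator: 1 for the 2-AFC detection task (0.5 lower asymptote)
GUESS = {"UprightFace": 0, "InvertedFace": 0, "Grating": 1}
ORIENTATION_TO_TASK = {"Upright": "UprightFace", "Inverted": "InvertedFace"}


@dataclass
class ObserverParams:
    """Per-cell logistic parameters for one observer.

    ``coef[(task, condition)] = (b0, b1)`` in logit units; slopes positive.
    """

    subject: int
    coef: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        for cell, (_, b1) in self.coef.items():
            if b1 <= 0:
                raise ValueError(f"slope must be positive in cell {cell}")


def response_probability(obs: ObserverParams, task: str, context: str,
                         x: float) -> float:
    """P(positive response) at scaled input ``x``: 0.5 g + (1 - 0.5 g) logistic(eta)."""
    b0, b1 = obs.coef[(task, context)]
    g = GUESS[task]
    return 0.5 * g + (1 - 0.5 * g) * expit(b0 + b1 * np.asarray(x, dtype=float))


def true_threshold(obs: ObserverParams, task: str, context: str) -> float:
    """Generating threshold -b0/b1: the 50 % point of the logistic core
    (75 % correct under a 0.5 guess rate)."""
    b0, b1 = obs.coef[(task, context)]
    if b1 == 0:
        raise ZeroDivisionError("threshold undefined for zero slope")
    return -b0 / b1


@dataclass
class PopulationConfig:
    """Ground-truth population for the synthetic study.

    Thresholds are stated on each task's analysis axis (z-dissimilarity for
    eye tasks, log10 contrast for detection).  Defaults emulate the group
    structure of the study being modeled: 59 observers; detection thresholds
    highest under an iso-oriented (Same) surround and close between Isolated
    and Different; upright eye matching with Same > Isolated > Different and
    Isolated nearer Same; inverted eye matching compressed, peaking at
    Isolated.
    """

    n_subjects: int = 59
    mean_threshold: dict = field(default_factory=lambda: {
        "UprightFace": {"Isolated": 0.21, "Different": -0.08, "Same": 0.49},
        "InvertedFace": {"Isolated": 0.42, "Different": 0.21, "Same": 0.31},
        "Grating": {"Isolated": -2.10, "Different": -2.20, "Same": -1.60},
    })
    # eye-task slopes in logit per z-unit of dissimilarity; detection slope in
    # logit per decade of contrast (2-AFC detection functions are steep,
    # Weibull beta ~ 3-4, i.e. ~10 logit/decade)
    mean_slope: dict = field(default_factory=lambda: {
        "UprightFace": 2.5, "InvertedFace": 2.0, "Grating": 10.0})
    threshold_sd: dict = field(default_factory=lambda: {
        "UprightFace": 0.35, "InvertedFace": 0.35, "Grating": 0.15})
    magnitude_sd: dict = field(default_factory=lambda: {
        "UprightFace": 0.25, "InvertedFace": 0.25, "Grating": 0.12})
    #: carry-over of Isolated / Different subject deviations into Same
    lambda_iso: float = 0.5
    lambda_diff: float = 0.3
    slope_sigma: float = 0.2          # lognormal SD of per-subject slope factor
    cell_slope_jitter: float = 0.05   # lognormal SD of per-cell slope jitter
    rho_magnitude: float = 0.6
    magnitude_pair: tuple[str, str] = ("UprightFace", "InvertedFace")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least three subjects")
        if not -1 <= self.rho_magnitude <= 1:
            raise ValueError("|rho_magnitude| must be <= 1")
        for d in (self.threshold_sd, self.magnitude_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("SDs must be non-negative")

    def magnitude_correlation(self) -> np.ndarray:
        """Correlation matrix of the latent magnitudes across the three tasks."""
        corr = np.eye(len(TASKS))
        i, j = (TASKS.index(t) for t in self.magnitude_pair)
        corr[i, j] = corr[j, i] = self.rho_magnitude
        return corr


@dataclass
class Population(Sequence):
    """Sampled observers plus the generating ground truth."""

    observers: list[ObserverParams]
    #: latent magnitude component per subject x task (z-threshold units)
    magnitudes: pd.DataFrame
    #: generating thresholds, long format: subject, task, condition, threshold
    true_thresholds: pd.DataFrame
    config: PopulationConfig

    def __len__(self) -> int:
        return len(self.observers)

    def __getitem__(self, i):
        return self.observers[i]


def sample_population(config: PopulationConfig) -> Population:
    """Draw a population of observers; reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    corr = config.magnitude_correlation()
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(TASKS)))
    except np.linalg.LinAlgError as err:
        raise ValueError("magnitude correlation matrix is not PSD") from err
    latent = rng.standard_normal((n, len(TASKS))) @ chol.T
    mag = latent * np.array([config.magnitude_sd[t] for t in TASKS])

    observers = []
    thr_rows = []
    for s in range(n):
        coef: dict[tuple[str, str], tuple[float, float]] = {}
        for ti, task in enumerate(TASKS):
            sd = config.threshold_sd[task]
            e_iso = rng.normal(0, sd)
            e_diff = rng.normal(0, sd)
            thr = {
                "Isolated": config.mean_threshold[task]["Isolated"] + e_iso,
                "Different": config.mean_threshold[task]["Different"] + e_diff,
                "Same": (config.mean_threshold[task]["Same"]
                         + config.lambda_iso * e_iso
                         + config.lambda_diff * e_diff
                         + mag[s, ti]),
            }
            slope_subj = config.mean_slope[task] * np.exp(
                config.slope_sigma * rng.standard_normal())
            for cond in CONDITIONS:
                b1 = slope_subj * np.exp(
                    config.cell_slope_jitter * rng.standard_normal())
                coef[(task, cond)] = (-thr[cond] * b1, b1)
                thr_rows.append(dict(subject=s, task=task, condition=cond,
                                     threshold=thr[cond]))
        observers.append(ObserverParams(subject=s, coef=coef))

    magnitudes = pd.DataFrame(mag, columns=list(TASKS))
    magnitudes.insert(0, "subject", np.arange(n))
    return Population(observers=observers, magnitudes=magnitudes,
                      true_thresholds=pd.DataFrame(thr_rows), config=config)


def dissimilarity_scaler(design: EyeMatchingDesign) -> tuple[float, float]:
    """Trial-weighted mean and SD of the design's dissimilarity values.

    These constants define the z-axis on which eye-matching observers are
    parameterized; they match the scaling the fitting stage recomputes from
    data because every simulated session presents the same trial multiset.
    """
    d = np.array([t.dissimilarity for t in design.trials], dtype=float)
    return float(d.mean()), float(d.std())


def run_eye_matching_session(obs: ObserverParams, design: EyeMatchingDesign,
                             seed: int) -> pd.DataFrame:
    """Simulate one observer's full eye-matching task (768 Bernoulli trials).

    Response coding: Different = 1, Same = 0.
    """
    rng = np.random.default_rng(seed)
    mean, sd = dissimilarity_scaler(design)
    rows = []
    for t in design.trials:
        task = ORIENTATION_TO_TASK[t.orientation]
        x = (t.dissimilarity - mean) / sd
        p = response_probability(obs, task, t.context, x)
        rows.append(dict(
            participant=obs.subject, task=task, context=t.context,
            x_raw=float(t.dissimilarity), response=int(rng.random() < p),
            block=t.block, trial_index=t.trial_index))
    return pd.DataFrame(rows)
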