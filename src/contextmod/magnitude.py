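"""Contextual-modulation magnitude statistic and Bayes-factor correlations.

The per-participant magnitude is the residual of a two-step
"regression of regressions" on z-scaled thresholds:

1. regress the Same-context and Different-context thresholds each on the
   Isolated (control) thresholds, removing variance shared with the control
   condition;
2. regress the Same residuals on the Different residuals.

The step-2 residuals isolate individual variation in the Same-context
threshold that neither the control condition nor the compared condition
explains — an individual-difference score uncontaminated by the compared
conditions' shared variance (unlike a simple subtraction).  Both steps
include an intercept so the result is location-invariant.

Cross-task association of these magnitudes is quantified by a Pearson
correlation with a Jeffreys-style Bayes factor: a stretched-beta prior on
the population correlation against a point null, integrated numerically
against the exact sampling density of r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats
from scipy.special import betaln, gammaln, hyp2f1

logger = logging.getLogger(__name__)

#: Jeffreys evidence categories: (strict lower bound on BF10, label)
EVIDENCE_BOUNDS = (
    (100.0, "decisive"),
    (30.0, "very strong"),
    (10.0, "strong"),
    (3.0, "substantial"),
    (1.0, "anecdotal"),
)


def evidence_label(bf10: float) -> str:
    """Jeffreys' verbal category for a Bayes factor.

    Bounds are strict (a BF10 of exactly 3 is still "anecdotal" for H1);
    values below 1 are categorized through 1/BF10 as evidence for H0.
    """
    if bf10 <= 0:
        raise ValueError("Bayes factor must be positive")
    if bf10 == 1.0:
        return "no evidence"
    bf, target = (bf10, "H1") if bf10 > 1 else (1.0 / bf10, "H0")
    for bound, label in EVIDENCE_BOUNDS:
        if bf > bound:
            return f"{label} for {target}"
    return f"anecdotal for {target}"


def ols_residuals(y, x) -> np.ndarray:
    """Residuals of OLS of ``y`` on ``x`` with an intercept."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D arrays of equal length")
    if y.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(model.resid)


@dataclass
class MagnitudeVector:
    """Per-participant contextual-modulation magnitudes for one task."""

    task: str
    participants: np.ndarray
    values: np.ndarray
    n_dropped: int = 0


def contextual_magnitude(thresholds: pd.DataFrame,
                         task: str) -> MagnitudeVector:
    """Two-step regression-of-regressions magnitudes for one task.

    ``thresholds`` is a threshold table in long format (columns participant,
    task, condition, threshold) on the scaled axis.  Participants missing any
    of the three context conditions are dropped listwise (count logged).
    """
    sub = thresholds[thresholds["task"] == task]
    wide = sub.pivot_table(index="participant", columns="condition",
                           values="threshold")
    needed = ["Isolated", "Different", "Same"]
    missing = [c for c in needed if c not in wide.columns]
    if missing:
        raise ValueError(f"missing context conditions for {task}: {missing}")
    complete = wide.dropna(subset=needed)
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning("contextual_magnitude(%s): dropped %d participants "
                       "with incomplete cells", task, n_dropped)
    if len(complete) < 3:
        raise ValueError("need at least three complete participants")
    r_same = ols_residuals(complete["Same"], complete["Isolated"])
    r_diff = ols_residuals(complete["Different"], complete["Isolated"])
    values = ols_residuals(r_same, r_diff)
    return MagnitudeVector(task=task,
                           participants=complete.index.to_numpy(),
                           values=values, n_dropped=n_dropped)


def _log_r_density(r: float, rho: float, n: int) -> float:
    """Log sampling density of the Pearson correlation r given rho (n pairs)."""
    lc = (np.log(n - 2) + gammaln(n - 1) - 0.5 * np.log(2 * np.pi)
          - gammaln(n - 0.5))
    ld = (0.5 * (n - 1) * np.log1p(-rho * rho)
          + 0.5 * (n - 4) * np.log1p(-r * r)
          - (n - 1.5) * np.log1p(-rho * r))
    h = hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)
    return lc + ld + np.log(h)


def _log_likelihood_ratio(r: float, rho: float, n: int) -> float:
    """log p(r | rho) - log p(r | 0); the r-only factors cancel, so this
    stays finite even at |r| = 1."""
    ld = (0.5 * (n - 1) * np.log1p(-rho * rho)
          - (n - 1.5) * np.log1p(-rho * r))
    h1 = hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)
    h0 = hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return ld + np.log(h1) - np.log(h0)


def _stretched_beta_logpdf(rho: float, scale: float) -> float:
    a = 1.0 / scale
    return (a - 1) * (np.log1p(rho) + np.log1p(-rho)) - betaln(a, a) - np.log(2.0) * (2 * a - 1)


@dataclass
class CorrelationBF:
    r: float
    bf10: float
    bf01: float
    n: int
    prior_scale: float
    evidence: str


def correlation_bf(a, b, prior_scale: float = 1.0 / 3.0) -> CorrelationBF:
    """Pearson correlation with a Bayes factor against the point null.

    The alternative places a stretched beta prior (shape 1/``prior_scale``)
    on the population correlation; BF10 is the ratio of the marginal
    likelihood of the observed r under that prior to its likelihood at
    rho = 0, computed by adaptive quadrature.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    n = a.size
    if n < 4:
        raise ValueError("need at least four pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(stats.pearsonr(a, b).statistic)

    def integrand(rho):
        return np.exp(_log_likelihood_ratio(r, rho, n)
                      + _stretched_beta_logpdf(rho, prior_scale))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        bf10, _ = integrate.quad(integrand, -1, 1, epsrel=1e-9, epsabs=0,
                                 limit=200)
    return CorrelationBF(r=r, bf10=float(bf10), bf01=float(1.0 / bf10), n=n,
                         prior_scale=prior_scale,
                         evidence=evidence_label(float(bf10)))
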