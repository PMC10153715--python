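"""Cross-task profile similarity with a permutation-anchored chance level.

Each participant contributes, per task, a 3-point threshold profile in the
fixed order (Isolated, Different, Same).  Similarity between two tasks is the
per-participant Pearson correlation of the two profiles, Fisher-Z transformed
(with r = +-1 clipped to +-0.99 first, since arctanh diverges at 1).

Because 3-point correlations carry a structural bias, the sample of Fisher-Z
values is tested not against zero but against an *empirical chance level*:
the average Fisher-Z obtained when each profile's condition order is replaced
by a random non-identity permutation, per subject, per task, per iteration.
A Jeffreys-Zellner-Siow (JZS) one-sample Bayes-factor t-test then weighs the
shift of the observed Fisher-Z sample away from that chance level.

Small-n identity worth knowing: for any two 3-vectors the Pearson r summed
over all six permutations of one of them is exactly zero (Pearson is linear
in the permuted, centered vector and the permutation sum is a constant
vector), so the mean over the five non-identity permutations is -r/5.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

PROFILE_ORDER = ("Isolated", "Different", "Same")
_CLIP = 0.99
_ALL_PERMS = tuple(itertools.permutations(range(3)))
#: permutations whose new ranks differ from the initial order (non-identity)
NON_IDENTITY_PERMS = tuple(p for p in _ALL_PERMS if p != (0, 1, 2))
#: stricter alternative reading: no element keeps its position
DERANGEMENTS = ((1, 2, 0), (2, 0, 1))


def fisher_z(r):
    """Variance-stabilizing arctanh transform, with +-1 clipped to +-0.99."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = np.clip(r, -1.0, 1.0)
    at_limit = np.abs(clipped) > 1 - 1e-12
    clipped = np.where(at_limit, np.sign(clipped) * _CLIP, clipped)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def profile_corr(a, b) -> float:
    """Pearson correlation of two threshold profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("profiles must be equal-length 1-D vectors (>= 3)")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant profile")
    return float(stats.pearsonr(a, b).statistic)


def _standardized(profiles: np.ndarray) -> tuple[np.ndarray, int]:
    """Center and unit-normalize rows; constant rows become zero (r -> 0)."""
    p = np.asarray(profiles, dtype=float)
    centered = p - p.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    constant = int((norms.ravel() == 0).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, centered / norms, 0.0)
    return out, constant


def profile_correlations(profiles_a, profiles_b) -> np.ndarray:
    """Per-subject profile correlations between two tasks.

    Constant profiles yield r = 0 (undefined Pearson) with a logged warning.
    """
    ua, ca = _standardized(profiles_a)
    ub, cb = _standardized(profiles_b)
    if ua.shape != ub.shape:
        raise ValueError("profile arrays must have matching shapes")
    if ca or cb:
        logger.warning("profile_correlations: %d constant profiles set to r=0",
                       ca + cb)
        warnings.warn(f"{ca + cb} constant profiles; correlations set to 0",
                      stacklevel=2)
    return np.einsum("ij,ij->i", ua, ub)


def empirical_chance(profiles_a, profiles_b, n_perm: int = 1000,
                     seed: int = 0, scheme: str = "non_identity",
                     average: str = "fisher_z") -> float:
    """Monte-Carlo chance level of the mean profile correlation (Fisher-Z).

    Per iteration, every subject's profile in *each* task is reordered by an
    independently drawn random permutation that differs from the original
    order; per-subject correlations are Fisher-Z transformed (or kept raw,
    ``average="raw"``) and averaged over subjects, and the iteration means
    are averaged.  Reproducible from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    perms = {"non_identity": NON_IDENTITY_PERMS,
             "derangement": DERANGEMENTS}.get(scheme)
    if perms is None:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if average not in ("fisher_z", "raw"):
        raise ValueError(f"unknown averaging mode {average!r}")
    ua, _ = _standardized(profiles_a)
    ub, _ = _standardized(profiles_b)
    if ua.shape != ub.shape:
        raise ValueError("profile arrays must have matching shapes")
    if ua.shape[0] < 2:
        raise ValueError("need at least two subjects")
    n_subj = ua.shape[0]
    perm_idx = np.asarray(perms)                     # (P, 3)
    # all permuted standardized profiles, precomputed: (n_subj, P, 3)
    pa = ua[:, perm_idx]
    pb = ub[:, perm_idx]
    rng = np.random.default_rng(seed)
    total = 0.0
    rows = np.arange(n_subj)
    for _ in range(n_perm):
        ia = rng.integers(0, len(perms), n_subj)
        ib = rng.integers(0, len(perms), n_subj)
        r = np.einsum("ij,ij->i", pa[rows, ia], pb[rows, ib])
        vals = fisher_z(r) if average == "fisher_z" else r
        total += vals.mean()
    return total / n_perm


@dataclass
class JZSResult:
    bf10: float
    bf01: float
    t: float
    n: int
    mean: float
    hdi_lower: float
    hdi_upper: float
    prior_scale: float


def jzs_one_sample(sample, mu0: float = 0.0,
                   prior_scale: float = np.sqrt(2) / 2,
                   hdi_prob: float = 0.95) -> JZSResult:
    """JZS Bayes-factor one-sample t-test of ``sample`` against ``mu0``.

    The alternative puts a Cauchy(0, ``prior_scale``) prior on the
    standardized effect size; BF10 is computed by adaptive quadrature of the
    Zellner-Siow mixture over the g-prior.  The posterior mean and HDI of the
    sample mean use the standard noninformative-prior Student-t posterior
    (a normal-likelihood approximation; symmetric, so the HDI coincides with
    the central interval).
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample of size >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    t = float((x.mean() - mu0) / (sd / np.sqrt(n)))
    nu = n - 1
    r2 = prior_scale ** 2

    def integrand(g):
        # Zellner-Siow: g ~ InverseGamma(1/2, r^2/2)
        ng1 = 1.0 + n * g
        log_lik = (-0.5 * np.log(ng1)
                   - 0.5 * (nu + 1) * np.log1p(t * t / (ng1 * nu)))
        log_prior = (0.5 * np.log(r2 / 2) - 0.5 * np.log(np.pi)
                     - 1.5 * np.log(g) - r2 / (2 * g))
        return np.exp(log_lik + log_prior)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        num, _ = integrate.quad(integrand, 0, np.inf, epsrel=1e-10, epsabs=0,
                                limit=300)
    log_null = -0.5 * (nu + 1) * np.log1p(t * t / nu)
    bf10 = float(num / np.exp(log_null))

    se = sd / np.sqrt(n)
    half = float(stats.t.ppf(0.5 + hdi_prob / 2, nu) * se)
    return JZSResult(bf10=bf10, bf01=1.0 / bf10, t=t, n=n,
                     mean=float(x.mean()), hdi_lower=float(x.mean() - half),
                     hdi_upper=float(x.mean() + half),
                     prior_scale=prior_scale)


@dataclass
class ProfileCorrResult:
    """Profile-similarity summary for one task pair."""

    task_a: str
    task_b: str
    fisher_z_values: np.ndarray
    mean_z: float
    hdi_lower: float
    hdi_upper: float
    empirical_chance: float
    bf10: float
    n_perm: int
    seed: int
    n_constant: int = 0

    @property
    def exceeds_chance(self) -> bool:
        return bool(self.hdi_lower > self.empirical_chance)


def profile_similarity(profiles_a, profiles_b, *, task_a: str = "A",
                       task_b: str = "B", n_perm: int = 1000, seed: int = 0,
                       scheme: str = "non_identity",
                       prior_scale: float = np.sqrt(2) / 2) -> ProfileCorrResult:
    """Full profile analysis for one task pair.

    Computes per-subject Fisher-Z profile correlations, the permutation
    chance level, and a JZS one-sample test of the Fisher-Z sample against
    that chance level.
    """
    r = profile_correlations(profiles_a, profiles_b)
    _, ca = _standardized(profiles_a)
    _, cb = _standardized(profiles_b)
    z = fisher_z(r)
    chance = float(empirical_chance(profiles_a, profiles_b, n_perm=n_perm,
                                    seed=seed, scheme=scheme))
    jzs = jzs_one_sample(z, mu0=chance, prior_scale=prior_scale)
    return ProfileCorrResult(
        task_a=task_a, task_b=task_b, fisher_z_values=z,
        mean_z=jzs.mean, hdi_lower=jzs.hdi_lower, hdi_upper=jzs.hdi_upper,
        empirical_chance=chance, bf10=jzs.bf10, n_perm=n_perm, seed=seed,
        n_constant=ca + cb)
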