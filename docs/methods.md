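# Methods

`contextmod` simulates and analyzes a dual-task psychophysics study of
contextual modulation: how the surround of a visual target changes the local
input strength needed to reach threshold performance, measured at a low level
(grating contrast detection inside an oriented surround) and a high level
(same/different matching of the eye region in upright and inverted face
pairs), in the same observers. The pipeline's question is an
individual-differences one: do the *magnitudes* and the *profiles* of
contextual modulation correlate across processing levels?

## Experimental designs

**Eye matching.** A same/different 2-AFC over morphed eye regions at five
dissimilarity levels (0, 24, 36, 53, 80 % of the morph continuum), crossed
with orientation (Upright, Inverted) and context (Same, Different, Isolated):
30 cells, 768 trials. Levels are realized by fixed morph pairs
(24 % -> 38/62, 36 % -> 32/68, 53 % -> 24/77, 80 % -> 10/90); 0 % trials
re-use the 10/32/62/77 % morphs. Each of the sixteen 48-trial blocks holds
24 "Same"-response and 24 "Different"-response trials balanced over all
factors; a seed only shuffles order within blocks. Face-pair identities are
abstract ids (1–16): counts and balance, not pixel content, drive the
analysis. A block-level accuracy flag is raised below 65 % correct; it is
informational only and never alters the design or data inclusion.

**Contrast detection.** Nine 80-trial blocks, three per context condition
(iso-oriented, orthogonal, none), consecutive blocks never sharing a
condition. Each block interleaves two independent 40-trial Psi staircases
drawing from 350 log-spaced Michelson contrasts on [0.001, 1].

## Stimulus operators

Grating scenes place four 3-deg raised-cosine target discs at 5-deg
eccentricity inside a 20-deg context disc (1 cpd, context contrast 0.25,
shared cosine phase; ramp width 0.5 deg, rendering at 16 px/deg — both
configurable and unclaimed as original values). Face-image preprocessing
primitives: affine normalization to mean luminance 0.52 and RMS contrast 0.12
(RMS = pixel SD on the 0..1 scale), pixelwise Pearson similarity, selection
of morph pairs within two sample SDs of the mean similarity, and iterative
phase scrambling for noise masks. The scrambling scheme — per iteration, add
a fresh Hermitian-antisymmetric random phase field, re-impose the original
amplitude spectrum, invert, clip to [0, 1] — is one concrete reading of
"iterative scrambling"; the testable contract is what we assert: amplitude
spectrum preserved within tolerance, output in range, decorrelated from the
source. The DC phase is never perturbed, so mean luminance survives.

## Synthetic observers

Every observer carries a logistic psychometric function per task x context
cell on the task's analysis axis — z-scored morph dissimilarity for eye
tasks (using the design's trial-weighted constants, mean 24.125 / SD 28.2),
log10 contrast for detection:

    P(response) = 0.5 g + (1 - 0.5 g) logistic(b0 + b1 x),   g = 1 only for detection.

There is no lapse parameter, deliberately mirroring the fitted model, so
parameter recovery is a clean benchmark: generating thresholds are exactly
-b0/b1.

Population defaults (59 observers) emulate the qualitative group structure
of the phenomenon: detection thresholds (log10 contrast) Isolated -2.10,
Different -2.20, Same -1.60 — surround suppression strongest under an
iso-oriented context; upright eye matching (z units) Isolated 0.21,
Different -0.08, Same 0.49, with Isolated nearer Same; inverted eye matching
compressed and peaking at Isolated (0.42, 0.21, 0.31). Between-subject
threshold SDs are 0.35 (faces) and 0.15 (detection); slopes are lognormal
around 2.5 / 2.0 logit per z-unit for upright/inverted and 10 logit per
decade for detection — 2-AFC contrast-detection functions are steep (a
Weibull shape parameter of 3–4 corresponds to roughly 10–12 logit/decade).
No real data stand behind these numbers; they are synthetic study conditions,
fixed once.

**Magnitude injection.** The Same-context threshold is built as
mu + 0.5 e_iso + 0.3 e_diff + m, where e_iso, e_diff are the subject's
Isolated/Different deviations and m is a latent magnitude component drawn,
across a designated task pair, with correlation `rho_magnitude` (default
0.6 between the two eye tasks). Because the two-step
regression-of-regressions removes exactly the parts of the Same threshold
predictable from Isolated and then Different, m is recoverable ground truth
by construction, which is what makes the magnitude statistic testable.

What the generator does **not** emulate: lapses, learning or fatigue,
sequential dependencies, reaction times, stimulus-specific (image-level)
difficulty, and any real-data covariance structure beyond the injected one.
Passing tests therefore certify the machinery — balanced designs, staircase
behavior, estimator calibration under the assumed model — not claims about
real observers.

## Psi staircase

Grid posterior over threshold alpha (61 points, log10 contrast in [-3, 0])
and slope beta (25 log-spaced points, 0.5–32 logit/decade), uniform prior;
internal model logistic with guess 0.5 and no lapse, matching the analysis
model rather than the Weibull sometimes used with this procedure. Stimulus
selection minimizes the expected posterior entropy over the two responses,
ties going to the lowest lattice index; the entropy decomposition reduces
selection to four matrix-vector products against precomputed likelihood
tables. Staircases within a block strictly alternate.

A session-level threshold pools the interleaved staircases (their trials are
conditionally independent given the parameters and share a flat prior, so
the pooled posterior is the normalized product) and, by default, takes the
MAP of the alpha marginal. Across 300 simulated 80-trial blocks under the
default population the three candidate estimators give bias/SD of
-0.047/0.092 (mean), -0.026/0.086 (median) and -0.003/0.075 (MAP) log units:
occasional shallow-slope posterior excursions drag a long lower tail that
biases the mean, so the MAP is the default; "mean" and "median" remain
options.

## Hierarchical psychometric model

All trials of all tasks enter one Bernoulli GLMM with the guess-aware link

    P(y=1) = 0.5 guess + (1 - 0.5 guess) logistic(eta)
    eta ~ x * task * condition + (x * task * condition || participant)

with dummy-coded predictors (reference: task UprightFace, condition
Isolated — thresholds are coding-invariant), uncorrelated random effects on
every term, Normal(0, 5) priors on fixed weights and LogNormal(0, 1) on
random-effect SDs (prior scales are our choices; only the families are
given). Upright and inverted eye matching are distinct task levels. Inputs
are z-scored per task (after log10 for contrast), trial-weighted over all
rows, stored for exact inversion; this yields the familiar roughly -3..3
axis.

Sampling is Hamiltonian Monte Carlo written for this model: non-centered
parameterization, analytic gradients, diagonal mass matrix estimated in
expanding warmup windows, dual-averaging step size (target acceptance 0.8),
jittered leapfrog paths, divergence accounting (energy error > 1000).
Split-R-hat and bulk ESS (via arviz) are computed for every parameter; a fit
with max R-hat > 1.05 or any divergence is flagged, never silently accepted.
Two profiles: the full one (4 chains x 6000 iterations, 3000 warmup, 12000
retained draws) and a fast one (2 chains x 1000/400, 1200 retained) for CI
and quick exploration; on the packaged demo both profiles yield threshold
tables that agree to well within their HDIs.

Thresholds are computed **per posterior draw** as -intercept/slope (the 50 %
point of the logistic core, i.e. 75 % correct under a 0.5 guess rate), then
summarized by posterior mean and 95 % HDI and back-transformed through the
stored scaler; -b0/b1 is nonlinear, so summarizing coefficients first would
bias it. Cells where >= 1 % of slope draws fall within 0.01 of zero are
flagged unstable. Condition contrasts are fixed-effects-only threshold
differences per draw, with an HDI-excludes-zero flag.

## Magnitude statistic and Bayes factors

Per task, the contextual-modulation magnitude is the residual of a two-step
regression on z-scaled thresholds: Same-on-Isolated and
Different-on-Isolated residuals first, then Same-residuals on
Different-residuals. Both steps include an intercept (needed for location
invariance of the downstream correlation); participants missing any context
cell are dropped listwise with a logged count.

Cross-task association: Pearson r with a Bayes factor integrating the exact
sampling density of r (Gauss hypergeometric form) against a stretched-beta
prior on the population correlation (default width 1/3; width 1 reproduces
the common stretched-uniform default, verified against an independent
implementation). BF01 = 1/BF10 by construction; Jeffreys categories
(anecdotal/substantial/strong/very strong/decisive at 1/3/10/30/100, strict
bounds) label the evidence.

## Profile analysis

Per subject and task, the 3-point threshold profile (Isolated, Different,
Same) is correlated across tasks; r = +-1 (within 1e-12) is clipped to
+-0.99 before Fisher-Z. Constant profiles (undefined Pearson) yield r = 0
with a warning and a separate count. The empirical chance level permutes, per
iteration and per subject, each task's profile with an independently drawn
non-identity permutation (5 of the 6; a stricter derangement scheme is a
config option), averages Fisher-Z values over subjects (raw-r averaging is an
option), then over 1000 iterations. A useful exact identity anchors the
tests: over all six permutations of one 3-vector the Pearson correlations sum
to zero, so the non-identity mean is -r/5, and with both sides permuted the
expectation is r/25. The Fisher-Z sample is tested against the chance level
with a JZS one-sample Bayes-factor t-test (Cauchy prior on effect size,
default scale sqrt(2)/2, Zellner-Siow g-mixture by quadrature; verified
against direct noncentral-t marginalization). The reported HDI of the mean
uses the standard Student-t posterior under a noninformative prior — a
normal-likelihood approximation, symmetric, hence identical to the central
interval.

## Numerical and degenerate-input policies

- Bernoulli probabilities are clipped at 1e-12 for likelihood evaluation.
- Psi posteriors renormalize after every update; a vanished posterior mass
  raises instead of silently flattening.
- All-0/all-1 response cells produce warnings (they carry no slope
  information on their own; the hierarchy still regularizes them).
- Every stochastic stage takes an explicit seed; identical configs reproduce
  reports bit-for-bit.
- HDIs use the shortest-sorted-window estimator on raw draws.

## Problem sizes in tests and reproduction

The packaged reproduction runs the full 59-observer study with the fast
sampler profile, 100-block staircase recovery, and a 20-seed magnitude round
trip; unit fits use 4–8 observers with reduced draws. These sizes are the
package's own defaults for a desk-scale run; the paper-scale sampler profile
is one flag away.

## Known limitations

- The HMC uses static trajectories, not NUTS; mixing is adequate for the
  packaged problem sizes but ESS per draw is below what a tuned NUTS would
  give, and fast-profile fits occasionally flag max R-hat slightly above
  1.05. Flags are surfaced, and the recovery benchmarks hold regardless.
- The correlation-BF quadrature relies on scipy's Gauss hypergeometric;
  extreme |r| -> 1 at very large n would need asymptotic handling.
- The grating renderer is a stimulus model (windowed sinusoids), not a
  display pipeline: no gamma, no temporal envelope.
- Real-data idiosyncrasies (lapses, criterion drift) are out of the
  generator's scope by design; conclusions about real observers require real
  data.
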