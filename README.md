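# contextmod

Contextual modulation — the influence of a surround on the processing of a
local visual target — operates at every level of the visual hierarchy, from
surround suppression of grating contrast in early cortex to the holistic
face context effects that make an eye region harder to judge inside a
stable face. `contextmod` is a Python package for researchers who want to
study, at the level of individual differences, whether these low- and
high-level contextual modulations share variance: it simulates a complete
dual-task psychophysics study and runs the full analysis chain on the
resulting (or any equivalently formatted) trial-level data.

The pipeline:

1. **Trial designs** — a 768-trial same/different eye-region matching task
   (5 morph-dissimilarity levels x 3 contexts x 2 orientations, balanced
   16 x 48-trial blocks) and a 720-trial contrast-detection task (9 blocks,
   two interleaved 40-trial adaptive staircases each).
2. **Psi staircases** — grid posterior over threshold and slope,
   expected-posterior-entropy stimulus selection over a 350-value
   log-contrast lattice.
3. **Synthetic observers** — per-cell logistic psychometrics
   `P = 0.5·guess + (1 − 0.5·guess)·logistic(b0 + b1·x)` with a controllable
   cross-task correlation of contextual-modulation magnitudes (recoverable
   ground truth).
4. **Hierarchical Bayesian fit** — one Bernoulli GLMM over both tasks,
   `eta ~ x·task·condition + (x·task·condition || participant)`, sampled by
   Hamiltonian Monte Carlo with analytic gradients; per-cell thresholds
   `−intercept/slope` (the 75 % point under a 0.5 guess rate, the 50 % point
   otherwise) with 95 % HDIs.
5. **Magnitude statistic** — two-step regression of regressions isolating
   each participant's contextual-modulation magnitude, correlated across
   tasks with a stretched-beta-prior Bayes factor.
6. **Profile analysis** — per-subject 3-point threshold-profile correlations
   (Fisher-Z), a permutation-based empirical chance level, and JZS
   one-sample Bayes-factor t-tests.

## Worked example

```python
from contextmod import pipeline

report = pipeline.run_pipeline(pipeline.PipelineConfig(out_dir="demo_run"))
print(report.recovery)
print(report.magnitude_correlations["UprightFace|InvertedFace"])
```

With the default configuration (59 synthetic observers, injected magnitude
correlation 0.6 between the two eye tasks, fast sampler profile) this prints

```
{'threshold_correlation': 0.9822, 'hdi_coverage': 0.9115, 'n_cells': 531,
 'magnitude_recovery': {'UprightFace': 0.896, 'InvertedFace': 0.843,
                        'Grating': 0.952}}
{'r': 0.720, 'bf10': 4.49e7, 'bf01': 2.23e-8, 'n': 59,
 'prior_scale': 0.333, 'evidence': 'decisive for H1'}
```

meaning: fitted thresholds track the generating `−b0/b1` at r = 0.98 with
91 % HDI coverage over all 531 participant x task x condition cells; the
regression-of-regressions magnitudes correlate with the injected latent
magnitudes at r = 0.84–0.95 per task; and the cross-task magnitude
correlation between upright and inverted eye matching comes out decisively
positive, as injected. Pairs without an injected correlation
(eye matching vs. contrast detection) come out near zero with Bayes factors
favoring the null.

The same stages are scriptable from the shell:

```bash
contextmod design --task eye --seed 1 --out eye_design.csv
contextmod simulate --seed 7 --out trials.csv
contextmod fit --trials trials.csv --profile fast --seed 1 --out thresholds.csv
contextmod magnitudes --thresholds thresholds.csv --out magnitudes.json
contextmod profiles --thresholds thresholds.csv --out profiles.json
contextmod run-all --seed 7 --out-dir demo_run
```

The `paper` sampler profile (4 chains x 6000 iterations, 3000 warmup,
12 000 retained draws) replaces `fast` for full-scale runs.

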