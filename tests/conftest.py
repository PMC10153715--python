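"""Shared fixtures: designs and small synthetic datasets reused across tests.

Everything is generated programmatically; expensive fits are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import contextmod as cm
from contextmod import fit as fit_mod
from contextmod import observers


@pytest.fixture(scope="session")
def eye_design():
    return cm.build_eye_matching_design(seed=1)


@pytest.fixture(scope="session")
def detection_design():
    return cm.build_detection_design(seed=3)


@pytest.fixture(scope="session")
def population8():
    return cm.sample_population(cm.PopulationConfig(n_subjects=8, seed=2))


# z-axis constants of the standard eye-matching design (trial-weighted
# dissimilarity mean/SD); observers are parameterized on this axis
_EYE_MEAN, _EYE_SD = observers.dissimilarity_scaler(
    cm.build_eye_matching_design(0))


def _natural_x(task, x_raw):
    """Map a raw input onto the axis the observer's coefficients live on."""
    if task == "Grating":
        return np.log10(x_raw)
    return (x_raw - _EYE_MEAN) / _EYE_SD


def constant_stimuli_trials(pop, tasks, n_reps=6, seed=0):
    """Method-of-constant-stimuli responses on each task's natural axis.

    Cheaper than running full sessions; used for unit-level fitting tests.
    """
    rng = np.random.default_rng(seed)
    grids = {
        "UprightFace": np.array([0.0, 24, 36, 53, 80]),
        "InvertedFace": np.array([0.0, 24, 36, 53, 80]),
        # raw contrasts whose log10 spans the detection thresholds
        "Grating": 10.0 ** np.linspace(-2.8, -0.8, 11),
    }
    rows = []
    for obs in pop:
        for task in tasks:
            for cond in observers.CONDITIONS:
                for x_raw in grids[task]:
                    p = cm.response_probability(obs, task, cond,
                                                _natural_x(task, x_raw))
                    y = rng.random(n_reps) < p
                    for v in y:
                        rows.append(dict(participant=obs.subject, task=task,
                                         context=cond, x_raw=float(x_raw),
                                         response=int(v)))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def grating_trials(population8):
    return constant_stimuli_trials(population8, ["Grating"], n_reps=8, seed=4)


@pytest.fixture(scope="session")
def grating_fit(grating_trials):
    scaled = cm.scale_inputs(grating_trials)
    cfg = fit_mod.SamplerConfig(chains=2, iterations=700, warmup=300,
                                n_leapfrog=16, seed=7)
    return cm.fit_model(scaled, cfg), scaled


@pytest.fixture(scope="session")
def mixed_fit(population8):
    pop = cm.sample_population(cm.PopulationConfig(n_subjects=4, seed=9))
    trials = constant_stimuli_trials(
        pop, list(observers.TASKS), n_reps=6, seed=5)
    scaled = cm.scale_inputs(trials)
    cfg = fit_mod.SamplerConfig(chains=2, iterations=450, warmup=200,
                                n_leapfrog=16, seed=11)
    return cm.fit_model(scaled, cfg), scaled, pop
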