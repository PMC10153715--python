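"""Deterministic trial-list generation for the two experiments.

Two tasks share one session structure:

* **Eye matching** — a same/different 2-AFC on the eye region of face pairs,
  method of constant stimuli over five morph-dissimilarity levels
  (0/24/36/53/80 %), crossed with orientation (Upright/Inverted) and context
  (Same/Different/Isolated).  768 trials over two sessions of eight 48-trial
  blocks.
* **Contrast detection** — report the side of a low-contrast horizontal
  grating target, context condition blocked (Same/Different/Isolated),
  nine blocks of 80 trials, each block interleaving two 40-trial adaptive
  staircases drawing from a 350-value log-spaced contrast pool.

Designs are fully balanced; a seed only shuffles presentation order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORIENTATIONS = ("Upright", "Inverted")
CONTEXTS = ("Same", "Different", "Isolated")

#: morph pair (percent of face B) realizing each nonzero dissimilarity level
MORPH_PAIRS: dict[int, tuple[int, int]] = {
    24: (38, 62),
    36: (32, 68),
    53: (24, 77),
    80: (10, 90),
}
NONZERO_LEVELS = tuple(sorted(MORPH_PAIRS))
#: morph percentages shown twice in 0 %-dissimilarity ("Same"-response) trials
ZERO_MORPHS = (10, 32, 62, 77)

N_EYE_TRIALS = 768
N_BLOCKS_PER_SESSION = 8
N_SESSIONS = 2
BLOCK_SIZE = 48

N_DETECTION_BLOCKS = 9
TRIALS_PER_DETECTION_BLOCK = 80
STAIRCASES_PER_BLOCK = 2
TRIALS_PER_STAIRCASE = 40
CONTRAST_POOL_SIZE = 350
CONTRAST_LO = 0.001
CONTRAST_HI = 1.0

FEEDBACK_ACCURACY_CUTOFF = 0.65


@dataclass(frozen=True)
class EyeTrial:
    """One eye-matching trial."""

    orientation: str
    context: str
    dissimilarity: int          # percent-morph units
    morph_a: int                # morph percentage of first target
    morph_b: int                # morph percentage of second target
    pair_id: int                # abstract face-pair identity, 1..16
    correct_response: str       # "Same" or "Different"
    block: int                  # global block index, 0..15
    session: int                # 1 or 2
    trial_index: int            # global presentation order, 0..767


@dataclass
class EyeMatchingDesign:
    trials: list[EyeTrial]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([t.__dict__ for t in self.trials])
        df.insert(0, "participant_id", "")
        df.insert(1, "task", "eye_matching")
        return df


@dataclass(frozen=True)
class DetectionBlock:
    context: str
    staircase_ids: tuple[int, int]
    n_trials: int = TRIALS_PER_DETECTION_BLOCK


@dataclass
class DetectionDesign:
    blocks: list[DetectionBlock]
    contrast_pool: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"block": i, "context": b.context,
             "staircase_a": b.staircase_ids[0], "staircase_b": b.staircase_ids[1],
             "n_trials": b.n_trials}
            for i, b in enumerate(self.blocks)
        ]
        return pd.DataFrame(rows)


def morph_pair_dissimilarity(a: float, b: float) -> float:
    """Dissimilarity of a morph pair: distance along the morph continuum.

    E.g. 24 % and 77 % morphs realize the 53 % dissimilarity level.
    """
    for v in (a, b):
        if not 0 <= v <= 100:
            raise ValueError(f"morph percentage {v!r} outside [0, 100]")
    return abs(a - b)


def contrast_pool(n: int = CONTRAST_POOL_SIZE,
                  lo: float = CONTRAST_LO,
                  hi: float = CONTRAST_HI) -> np.ndarray:
    """Strictly increasing log-spaced lattice of candidate Michelson contrasts."""
    if n < 2:
        raise ValueError("need at least two lattice values")
    if not 0 < lo < hi <= 1:
        raise ValueError(f"invalid contrast bounds ({lo}, {hi}]")
    return np.geomspace(lo, hi, n)


def block_feedback(block_accuracy: float) -> bool:
    """Whether the attentiveness notification is shown after a block.

    Raised iff accuracy is strictly below 65 %; purely informational.
    """
    if not 0 <= block_accuracy <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    return block_accuracy < FEEDBACK_ACCURACY_CUTOFF


def _block_trials(block: int, rng: np.random.Generator) -> list[dict]:
    """Unordered trial specs for one 48-trial block.

    Per orientation x context cell: four 0 %-dissimilarity trials (one per
    morph value shown in "Same"-response trials) and one trial per nonzero
    level.  Target-order of nonzero pairs alternates across blocks so each
    morph of a pair leads equally often.
    """
    specs: list[dict] = []
    for ci, (orientation, context) in enumerate(
            itertools.product(ORIENTATIONS, CONTEXTS)):
        for mi, morph in enumerate(ZERO_MORPHS):
            specs.append(dict(
                orientation=orientation, context=context, dissimilarity=0,
                morph_a=morph, morph_b=morph,
                pair_id=1 + (block * 4 + mi + ci) % 16,
                correct_response="Same"))
        for li, level in enumerate(NONZERO_LEVELS):
            a, b = MORPH_PAIRS[level]
            if (block + ci + li) % 2:
                a, b = b, a
            specs.append(dict(
                orientation=orientation, context=context, dissimilarity=level,
                morph_a=a, morph_b=b,
                pair_id=1 + (block + ci * 4 + li) % 16,
                correct_response="Different"))
    rng.shuffle(specs)
    return specs


def build_eye_matching_design(seed: int) -> EyeMatchingDesign:
    """Generate the 768-trial eye-matching design, order shuffled from ``seed``.

    The trial multiset is invariant over seeds: 30 orientation x context x
    dissimilarity cells, 64 zero-dissimilarity and 16-per-nonzero-level trials
    in each orientation x context cell, blocks of 48 balanced across all
    factors.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    trials: list[EyeTrial] = []
    index = 0
    for block in range(N_SESSIONS * N_BLOCKS_PER_SESSION):
        for spec in _block_trials(block, rng):
            trials.append(EyeTrial(
                block=block, session=block // N_BLOCKS_PER_SESSION + 1,
                trial_index=index, **spec))
            index += 1
    return EyeMatchingDesign(trials=trials, seed=seed)


def build_detection_design(seed: int) -> DetectionDesign:
    """Generate the 9-block contrast-detection design.

    Three blocks per context condition; block order randomized under the
    constraint that consecutive blocks never share a condition.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    conditions = list(CONTEXTS) * 3
    while True:
        order = list(rng.permutation(conditions))
        if all(a != b for a, b in zip(order, order[1:])):
            break
    blocks = [
        DetectionBlock(context=ctx, staircase_ids=(2 * i, 2 * i + 1))
        for i, ctx in enumerate(order)
    ]
    return DetectionDesign(blocks=blocks, contrast_pool=contrast_pool(),
                           seed=seed)
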