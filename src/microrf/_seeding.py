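"""Deterministic seed fan-out.

A single pipeline seed is expanded into independent per-stage streams via
``numpy.random.SeedSequence`` spawn keys.  Each stage owns a fixed key, so
adding a new stage never perturbs the draws of existing ones, and replaying
one stage in isolation reproduces its in-pipeline randomness.
"""

from __future__ import annotations

import numpy as np

#: Fixed spawn keys per randomised stage.  Never renumber; append only.
STAGE_KEYS = {
    "simulate": 0,
    "rarefy": 1,
    "splits_stage1": 2,
    "splits_stage2": 3,
    "forest_stage1": 4,
    "forest_stage2": 5,
    "permutation": 6,
}


def stage_seed_sequence(seed: int, stage: str) -> np.random.SeedSequence:
    """Return the SeedSequence owned by *stage* under the pipeline *seed*."""
    try:
        key = STAGE_KEYS[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(STAGE_KEYS)}")
    return np.random.SeedSequence(entropy=seed, spawn_key=(key,))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for *stage* derived from the pipeline *seed*."""
    return np.random.default_rng(stage_seed_sequence(seed, stage))


def child_ints(ss: np.random.SeedSequence, n: int) -> list[int]:
    """Draw *n* independent 31-bit integers (e.g. sklearn random_state)."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
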