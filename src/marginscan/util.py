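"""Small shared helpers: deterministic seed fan-out and config hashing."""

from __future__ import annotations

import numpy as np

SCHEMA_VERSION = "1"

#: Named stages of the scanner pipeline, in the order they draw randomness.
STAGES = (
    "phantom",
    "render",
    "reconstruct",
    "plan",
    "simulate",
    "preprocess",
    "unmix",
    "classify",
    "mc",
    "study",
)


def spawn_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed (< 2**31) from one global seed.

    Uses :class:`numpy.random.SeedSequence` with the stage index as spawn
    key, so stages never collide and every stage is reproducible from the
    single archived run seed.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(spawn_seed(seed, stage))
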