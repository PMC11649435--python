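"""Seed policy: one master seed, child generators by stable per-stage offsets.

Every stochastic stage derives its own :class:`numpy.random.Generator` from
the master seed and a fixed stage key, so adding or re-running one stage never
perturbs the random stream of another.
"""

from __future__ import annotations

import numpy as np

# Stable stage offsets; never reorder or reuse.
STAGE_OFFSETS = {
    "labels": 0,
    "counts": 1,
    "clinical": 2,
    "dpa": 3,
    "pipeline": 4,
}


def child_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return the generator for ``stage`` derived from ``master_seed``."""
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown rng stage {stage!r}; known: {sorted(STAGE_OFFSETS)}")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(STAGE_OFFSETS[stage],))
    return np.random.default_rng(ss)
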