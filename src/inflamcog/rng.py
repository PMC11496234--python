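"""Deterministic random-stream management.

Every randomized stage of the pipeline draws from its own substream, derived
from the single user-facing seed and a fixed per-stage key. Changing the
number of bootstrap resamples therefore cannot perturb, say, the Gaussian
null test: the streams are independent by construction.
"""

from __future__ import annotations

import numpy as np

# Fixed stage registry: appending new stages is safe, reordering is not.
_STAGE_KEYS = {
    "cohort": 0,
    "missingness": 1,
    "null_test": 2,
    "bootstrap": 3,
    "permutation": 4,
    "lmm_sim": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated generator for a named pipeline stage."""
    try:
        key = _STAGE_KEYS[stage]
    except KeyError:
        raise ValueError(f"unknown rng stage {stage!r}; known: {sorted(_STAGE_KEYS)}")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
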