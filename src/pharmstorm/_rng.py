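"""Seed plumbing.

Every stochastic entry point accepts ``seed`` as an int, a Generator, or
None.  Pipeline stages derive independent substreams from one global seed by
hashing the stage name, so adding or reordering stages never perturbs the
random stream of another stage.
"""
from __future__ import annotations

import zlib

import numpy as np


def as_generator(seed: "int | np.random.Generator | None") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stage_seed(global_seed: int, stage_name: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    mix = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, zlib.crc32(stage_name.encode())])
    return int(mix.generate_state(1)[0] % (2**31))
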