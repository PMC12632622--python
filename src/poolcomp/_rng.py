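"""Seed management.

Every stochastic stage derives its generator from one user-facing integer
seed plus a stage label, so stages are independently reproducible and
re-running one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def spawn_rng(seed: int, *path: object) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and a label path.

    The labels are hashed (CRC32) into a SeedSequence spawn key, giving a
    stable counter-based split: ``spawn_rng(1, "reads", 3)`` is the same
    stream in every process and release, and distinct paths give
    independent streams.
    """
    key = tuple(zlib.crc32(repr(p).encode()) for p in path)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
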