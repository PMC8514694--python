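"""Deterministic seed splitting.

Every stochastic operation takes one integer seed and derives an
independent child stream per named purpose via ``numpy``'s
``SeedSequence`` spawn keys. The purpose string is hashed with CRC32 so
the mapping is stable across sessions and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, *path: "str | int") -> np.random.SeedSequence:
    key = tuple(
        p if isinstance(p, int) else zlib.crc32(p.encode()) for p in path
    )
    return np.random.SeedSequence(entropy=seed, spawn_key=key)


def rng_for(seed: int, *path: "str | int") -> np.random.Generator:
    """Generator for stream ``path`` under root ``seed``."""
    return np.random.default_rng(child_seed(seed, *path))
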