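"""Deterministic random-stream management.

Every source of randomness in the package is derived from a single master
seed.  Named substreams keep components (splitting, weight initialisation,
dropout, data generation) independent: adding draws to one stream never
perturbs another, so results are exactly repeatable run to run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a master seed.

    The stream is keyed by a hash of ``name`` via SeedSequence spawn keys,
    so streams for distinct names are statistically independent and stable
    across runs and platforms.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
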