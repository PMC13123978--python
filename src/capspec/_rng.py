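"""Deterministic child-seed derivation.

All stochastic operations take a single master seed; each operation derives
its own child generator by hashing (master seed, operation name).  Adding a
new operation therefore never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(master_seed: int, name: str) -> int:
    """Stable 31-bit child seed for the operation ``name``."""
    h = zlib.crc32(f"{int(master_seed)}:{name}".encode("utf-8"))
    return int(h & 0x7FFFFFFF)


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """Generator seeded from (master seed, operation name)."""
    return np.random.default_rng(child_seed(master_seed, name))
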