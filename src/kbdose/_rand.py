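"""Deterministic named substreams derived from one run seed.

Every source of randomness in the package (fold assignment, voxel sampling,
weight initialization, phantom geometry, dose noise) draws from a child
seed obtained by hashing the run seed together with a descriptive key path,
so reruns with the same seed are bit-identical and substreams never collide
by accident.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, *keys) -> int:
    """A 31-bit child seed deterministically derived from ``seed`` and a
    key path (strings/ints)."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(seed)).encode())
    for k in keys:
        h.update(b"/")
        h.update(str(k).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def child_rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *keys))
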