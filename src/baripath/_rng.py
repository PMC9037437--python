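"""Seed-substream derivation.

Every stochastic stage derives its own generator from the single global
seed and a stage name, so inserting or re-running one stage never perturbs
the random stream of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream_seed", "substream"]

_MOD = 2**31


def substream_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from ``seed`` and a stage name."""
    digest = hashlib.blake2b(f"{int(seed)}:{name}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % _MOD


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a ``numpy`` Generator seeded for the named stage."""
    return np.random.default_rng(substream_seed(seed, name))
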