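"""Deterministic derivation of child seeds from a single master seed.

Every stochastic stage of the pipeline draws its randomness from a
``numpy.random.Generator`` seeded through :func:`child_seed`, keyed by the
master seed plus a tuple of string/int labels (tissue, gene, stage, run
index ...).  This makes serial and re-ordered execution produce identical
streams, and lets a single integer reproduce an entire run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(master: int, *keys: object) -> int:
    """Derive a stable 31-bit child seed from ``master`` and a key path.

    The derivation hashes the decimal master seed together with the
    ``repr`` of each key through BLAKE2b, so it is stable across Python
    versions and platforms (unlike ``hash()``).
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master)).encode())
    for k in keys:
        h.update(b"\x1f")
        h.update(repr(k).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def rng_for(master: int, *keys: object) -> np.random.Generator:
    """A PCG64 generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *keys))
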