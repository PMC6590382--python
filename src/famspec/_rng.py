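"""Deterministic random-stream derivation.

One root seed per pipeline run; every randomized operation draws from a
child stream keyed by a short label, so stages are reproducible in
isolation and independent of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, int):
        return key & 0x7FFFFFFF
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF


def child_seed(seed: int, *keys: str | int) -> int:
    """Derive a deterministic 31-bit child seed from a root seed and labels."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Generator for the child stream identified by ``keys``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)])
    )
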