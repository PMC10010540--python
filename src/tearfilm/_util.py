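"""Seed fan-out and small shared helpers."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "stable_hash32"]


def stable_hash32(*parts: object) -> int:
    """Stable 31-bit hash of a tuple of printable parts (independent of PYTHONHASHSEED)."""
    digest = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def substream(seed: int, *names: object) -> np.random.Generator:
    """Derive a named, reproducible random stream from a single top-level seed.

    Every stochastic stage of the pipeline pulls its generator through this
    function so stages can be re-run independently yet reproducibly.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         stable_hash32(*names)]))
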