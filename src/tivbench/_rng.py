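"""Deterministic RNG sub-streams.

One top-level seed per study; each pipeline stage derives its own independent
stream from (seed, stage label) so that adding a stage never perturbs the
draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for ``label`` derived deterministically from ``seed``.

    The label is hashed with CRC-32 (stable across platforms and sessions,
    unlike Python's ``hash``) and combined with the seed in a SeedSequence.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
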