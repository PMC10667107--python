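"""Seed-sequence plumbing shared by all generators.

Every generator derives an independent NumPy stream from (root seed, stage
name), so adding a stage or re-ordering calls never perturbs another stage's
draws while the whole pipeline stays reproducible from a single integer.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for *stage* derived from the root *seed*.

    The stage name is folded in through a CRC32 so streams for different
    stages are statistically independent, and the same (seed, stage) pair is
    bit-reproducible across sessions.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
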