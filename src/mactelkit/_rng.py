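"""Deterministic per-stage random streams.

One master seed drives the whole pipeline; each named stage gets an
independent child stream so a stage can be regenerated without consuming
randomness that belongs to another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a child seed sequence for a named stage.

    The stage name is folded in through a CRC32 so the mapping is stable
    across sessions and platforms, unlike ``hash()``.
    """
    return np.random.SeedSequence(entropy=int(master_seed) % (2**31),
                                  spawn_key=(zlib.crc32(stage.encode()),))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """A fresh :class:`numpy.random.Generator` for one pipeline stage."""
    return np.random.default_rng(stage_seed(master_seed, stage))
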