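"""Seed fan-out and small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a stage/participant seed from a master seed.

    Hash-based fan-out keeps random streams of different pipeline stages
    (and different participants within a stage) statistically independent,
    instead of coupling them through one shared generator.  The result is
    always < 2**31 so it can be fed to any library RNG.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode()), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage, index))
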