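"""Seed plumbing: named per-stage substreams from a single master seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic 31-bit seed for a named stage.

    Adding a new stage never perturbs the draws of existing stages because
    each stream is keyed by (seed, crc32(stage)) rather than by draw order.
    """
    return zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF ^ 0


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for one named stage of a run."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stage_seed(seed, stage)]))
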