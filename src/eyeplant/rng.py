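"""Deterministic random-number substreams.

A single user-facing seed fans out into named substreams (targets, PRBS,
fixtures, ...) so that each component of a run is independently reproducible:
changing how many targets are drawn does not perturb the excitation signal,
and vice versa.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for"]


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Generator for the named substream of ``seed``."""
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
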