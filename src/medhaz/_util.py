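"""Shared small utilities: seeded substreams and reporting-style rounding."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "round_half_away"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from a master seed.

    Every stochastic stage of the pipeline (cohort generation, bootstrap,
    simulation studies) draws from its own named stream so that adding a
    stage never perturbs the draws of another.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention of printed results tables).

    numpy's default rounds half to even, which would print 1.45 as 1.4;
    results tables print it as 1.5.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out.item() if out.ndim == 0 else out
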