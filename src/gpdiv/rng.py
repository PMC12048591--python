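"""Reproducible named random-number streams.

A single top-level seed is expanded into independent substreams keyed by
(name, index) through :class:`numpy.random.SeedSequence`, so parallel or
re-ordered execution of lineages/sites draws from statistically independent
generators while remaining bit-reproducible from the one seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "rng_streams"]


def _name_key(name: str) -> int:
    # stable across processes and Python versions (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def stream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """An independent generator for substream ``(name, index)`` of ``seed``."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_name_key(name), index))
    return np.random.default_rng(ss)


def rng_streams(seed: int, n_streams: int, name: str = "stream") -> list[np.random.Generator]:
    """``n_streams`` independent generators derived from one seed."""
    return [stream(seed, name, i) for i in range(n_streams)]
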