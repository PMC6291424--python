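"""Seed derivation.

All stochastic steps derive their generators from one top-level integer
seed via :class:`numpy.random.SeedSequence` spawn keys. A substream is
addressed by a (stream name, counter...) tuple; stream names are hashed to
stable integers so the scheme is independent of call order.
"""
from __future__ import annotations

import zlib

import numpy as np

# Named substreams used by the package.
STREAM_TRANSCRIPTS = "transcripts"
STREAM_COVERAGE = "coverage"
STREAM_MATRIX = "matrix"
STREAM_QPCR = "qpcr"
STREAM_GSEA = "gsea"
STREAM_SUBSET = "subset"
STREAM_OBSERVED = "observed"


def _stream_key(name: str) -> int:
    return zlib.crc32(name.encode("utf8"))


def seed_sequence(seed: int, stream: str, *counters: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(_stream_key(stream), *counters))


def generator(seed: int, stream: str, *counters: int) -> np.random.Generator:
    """Generator for substream ``(stream, *counters)`` of ``seed``."""
    return np.random.Generator(np.random.PCG64(seed_sequence(seed, stream, *counters)))
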