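"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open (BED convention) throughout. GTF input
is converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class InputError(ValueError):
    """Raised when an input value or file violates a documented precondition."""


class FormatError(InputError):
    """Raised when a file cannot be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InputError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise InputError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise InputError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A transcript: exon geometry, one 3'-UTR, and miRNA binding sites.

    ``exons`` hold the coding/exonic intervals used as the ratio denominator;
    every binding site must lie inside ``utr3``.
    """

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    utr3: GenomicInterval
    sites: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise InputError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: (e.chrom, e.start))
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise InputError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        for s in self.sites:
            if not self.utr3.contains(s):
                raise InputError(
                    f"{self.transcript_id}: site {s} not contained in 3'-UTR {self.utr3}"
                )
        self.sites = sorted(self.sites, key=lambda s: s.start)


class CoverageTrack:
    """Dense per-base read-depth track.

    Backed by one float array per chromosome; positions outside every stored
    array have depth 0. Depth values may be fractional (bedGraph reals).
    """

    def __init__(self, arrays: dict[str, np.ndarray] | None = None):
        self._arrays: dict[str, np.ndarray] = {}
        if arrays:
            for chrom, arr in arrays.items():
                self.set_chrom(chrom, arr)

    def set_chrom(self, chrom: str, depths: np.ndarray) -> None:
        arr = np.asarray(depths, dtype=float)
        if arr.ndim != 1:
            raise InputError("per-chromosome depth array must be 1-D")
        if np.any(arr < 0):
            raise InputError("coverage depths must be non-negative")
        self._arrays[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted(self._arrays)

    def depths(self, iv: GenomicInterval) -> np.ndarray:
        """Per-base depths over ``iv``, zero-filled outside the stored track."""
        out = np.zeros(len(iv), dtype=float)
        arr = self._arrays.get(iv.chrom)
        if arr is None:
            return out
        lo = min(iv.start, arr.size)
        hi = min(iv.end, arr.size)
        if hi > lo:
            out[: hi - lo] = arr[lo:hi]
        return out

    def pooled_depths(self, ivs: Iterable[GenomicInterval]) -> np.ndarray:
        parts = [self.depths(iv) for iv in ivs]
        if not parts:
            return np.zeros(0)
        return np.concatenate(parts)

    def mean(self, iv: GenomicInterval) -> float:
        return float(self.depths(iv).mean())

    def scaled(self, c: float) -> "CoverageTrack":
        if c <= 0:
            raise InputError("scale factor must be > 0")
        return CoverageTrack({k: v * c for k, v in self._arrays.items()})


# Bin labels for the site-presence ratio (cutpoints 0.5 and 0.9).
BIN_HIGH = "high"
BIN_MID = "mid"
BIN_LOW = "low"
BIN_NOT_DETECTED = "not_detected"
BINS = (BIN_HIGH, BIN_MID, BIN_LOW, BIN_NOT_DETECTED)


@dataclass
class SitePresence:
    """Per-gene binding-site presence summary.

    ``max_ratio`` is the maximal ratio of mean site depth to median exon
    depth over all annotated sites; it is ``None`` for genes whose transcript
    is not detectable (``expressed`` False, bin ``not_detected``).
    """

    gene_id: str
    median_exon_depth: float
    site_ratios: list[float]
    max_ratio: float | None
    expressed: bool
    bin: str
    best_site: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.bin not in BINS:
            raise InputError(f"unknown bin {self.bin!r}")
        if self.expressed == (self.bin == BIN_NOT_DETECTED):
            raise InputError("bin is not_detected iff gene is not expressed")


@dataclass
class GeneSet:
    """A named set of gene identifiers (GMT record)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        if not name:
            raise InputError("gene set name must be non-empty")
        self.name = name
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class RankedList:
    """Genes ordered by a differential-expression metric, descending.

    Ties in the metric are broken by lexicographic gene id so the order is
    deterministic.
    """

    genes: np.ndarray  # dtype=object / str, unique
    scores: np.ndarray  # float, descending

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.genes.size != self.scores.size:
            raise InputError("genes and scores must have equal length")
        if len(set(self.genes.tolist())) != self.genes.size:
            raise InputError("ranked list contains duplicate genes")
        if np.any(np.diff(self.scores) > 0):
            raise InputError("scores must be sorted in descending order")

    def __len__(self) -> int:
        return int(self.genes.size)

    @classmethod
    def from_unsorted(cls, genes: Sequence[str], scores: Sequence[float]) -> "RankedList":
        g = np.asarray(genes)
        s = np.asarray(scores, dtype=float)
        order = np.lexsort((g, -s))  # primary: score desc; secondary: gene id asc
        return cls(g[order], s[order])


@dataclass
class GseaResult:
    """Outcome of one gene-set enrichment run on one ranked list."""

    set_name: str
    es: float
    running_scores: np.ndarray
    hit_positions: np.ndarray  # 0-based ranks of set members in the list
    leading_edge: list[str]
    nes: float | None = None
    nominal_p: float | None = None
    n_members_used: int = 0
    n_members_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "set": self.set_name,
            "es": self.es,
            "nes": self.nes,
            "nominal_p": self.nominal_p,
            "n_members_used": self.n_members_used,
            "n_members_dropped": self.n_members_dropped,
            "leading_edge": list(self.leading_edge),
        }


@dataclass
class ResamplingOutcome:
    """Result of the random-subset resampling significance procedure."""

    observed_nes: np.ndarray
    null_nes: np.ndarray
    welch_t: float
    welch_df: float
    welch_p: float
    empirical_percentile: float
    empirical_p: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_nes": [float(x) for x in self.observed_nes],
            "null_nes": [float(x) for x in self.null_nes],
            "welch_t": self.welch_t,
            "welch_df": self.welch_df,
            "welch_p": self.welch_p,
            "empirical_percentile": self.empirical_percentile,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
        }
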