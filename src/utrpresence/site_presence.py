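"""Binding-site presence from RNA-seq coverage.

Activated, proliferating T helper cells shorten their 3'-UTRs through
alternative polyadenylation, so a predicted miRNA binding site may simply
be absent from most of the mRNA molecules a gene actually expresses. The
statistic computed here estimates, per gene, the fraction of expressed
transcripts that still carry a site: the coverage of the binding-site
region in the 3'-UTR divided by the median per-base coverage of the
transcript's exons. With several annotated sites the maximal ratio is kept.
Genes are then binned at ratio cutpoints 0.5 and 0.9 and the PT_50 set
(ratio >= 0.5 among expressed genes) is formed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import RawTranscript, read_annotation, read_bed_sites
from .types import (
    BIN_HIGH,
    BIN_LOW,
    BIN_MID,
    BIN_NOT_DETECTED,
    BINS,
    CoverageTrack,
    GeneSet,
    GenomicInterval,
    InputError,
    SitePresence,
    TranscriptModel,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_EXPRESSED_DEPTH = 1.0
BIN_CUT_LOW = 0.5   # PT_50 threshold; mid bin is [0.5, 0.9]
BIN_CUT_HIGH = 0.9  # high bin is ratio > 0.9 (exclusive, "ratio > 0.9")


@dataclass
class DroppedSite:
    """A BED site contained in no transcript's 3'-UTR (reported, not used)."""

    site: GenomicInterval
    reason: str = "outside every 3'-UTR"


def select_isoform(candidates: list[RawTranscript]) -> RawTranscript:
    """Pick one transcript per gene: the longest annotated 3'-UTR.

    Ties are broken by lexicographically smallest transcript id, so the
    choice is deterministic.
    """
    with_utr = [c for c in candidates if c.utr_span() is not None]
    if not with_utr:
        raise InputError(
            f"gene {candidates[0].gene_id}: no transcript has an annotated 3'-UTR"
        )
    return min(with_utr, key=lambda c: (-len(c.utr_span()), c.transcript_id))


def load_transcripts(
    annotation_source: str, sites_source: str
) -> tuple[list[TranscriptModel], list[DroppedSite]]:
    """Build transcript models from annotation + BED sites.

    One model per gene (isoform with the longest 3'-UTR); each site is
    assigned to every transcript whose 3'-UTR fully contains it. Sites
    contained in no 3'-UTR are returned as dropped records.
    """
    raw = read_annotation(annotation_source)
    sites = read_bed_sites(sites_source)

    by_gene: dict[str, list[RawTranscript]] = {}
    for r in raw:
        by_gene.setdefault(r.gene_id, []).append(r)

    models: list[TranscriptModel] = []
    for gene_id in sorted(by_gene):
        candidates = by_gene[gene_id]
        try:
            chosen = select_isoform(candidates)
        except InputError:
            log.warning("gene %s skipped: no 3'-UTR annotated", gene_id)
            continue
        if not chosen.exons:
            log.warning("gene %s skipped: no exons annotated", gene_id)
            continue
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=chosen.transcript_id,
                exons=list(chosen.exons),
                utr3=chosen.utr_span(),
                sites=[],
            )
        )

    dropped: list[DroppedSite] = []
    for site in sites:
        owners = [m for m in models if m.utr3.contains(site)]
        if not owners:
            dropped.append(DroppedSite(site))
            continue
        for m in owners:
            m.sites.append(site)
    for m in models:
        m.sites = sorted(m.sites, key=lambda s: s.start)
    if dropped:
        log.warning("%d binding sites fell outside every 3'-UTR", len(dropped))
    return models, dropped


def median_exon_depth(t: TranscriptModel, cov: CoverageTrack) -> float:
    """Median per-base depth pooled across all exon intervals."""
    depths = cov.pooled_depths(t.exons)
    if depths.size == 0:
        return 0.0
    return float(np.median(depths))


def _site_depth(cov: CoverageTrack, site: GenomicInterval,
                aggregator: str, flank: int) -> float:
    if flank:
        site = GenomicInterval(
            site.chrom, max(0, site.start - flank), site.end + flank, site.strand
        )
    depths = cov.depths(site)
    if aggregator == "mean":
        return float(depths.mean())
    if aggregator == "median":
        return float(np.median(depths))
    raise InputError(f"unknown site aggregator {aggregator!r}")


def classify_ratio(max_ratio: float) -> str:
    if max_ratio > BIN_CUT_HIGH:
        return BIN_HIGH
    if max_ratio >= BIN_CUT_LOW:
        return BIN_MID
    return BIN_LOW


def site_presence(
    t: TranscriptModel,
    cov: CoverageTrack,
    min_expressed_depth: float = DEFAULT_MIN_EXPRESSED_DEPTH,
    aggregator: str = "mean",
    flank: int = 0,
) -> SitePresence:
    """Per-gene presence ratio: site depth over median exon depth.

    A gene counts as expressed when its median exon depth reaches
    ``min_expressed_depth``; otherwise ratios are undefined and the gene
    is binned ``not_detected``. The per-site depth aggregator defaults to
    the arithmetic mean over the site interval. Ratios are not capped at
    1; noise-driven values > 1 land in the high bin. Ties in the maximum
    are resolved toward the first site in genomic order.
    """
    med = median_exon_depth(t, cov)
    expressed = med >= min_expressed_depth
    if not expressed:
        return SitePresence(
            gene_id=t.gene_id,
            median_exon_depth=med,
            site_ratios=[],
            max_ratio=None,
            expressed=False,
            bin=BIN_NOT_DETECTED,
        )
    if not t.sites:
        # an expressed transcript with no annotated site trivially carries
        # the site in none of its molecules
        log.warning("gene %s expressed but has no annotated sites", t.gene_id)
        return SitePresence(
            gene_id=t.gene_id,
            median_exon_depth=med,
            site_ratios=[],
            max_ratio=0.0,
            expressed=True,
            bin=BIN_LOW,
        )
    ratios = [_site_depth(cov, s, aggregator, flank) / med for s in t.sites]
    best = int(np.argmax(ratios))  # argmax returns the first maximiser
    max_ratio = float(ratios[best])
    return SitePresence(
        gene_id=t.gene_id,
        median_exon_depth=med,
        site_ratios=[float(r) for r in ratios],
        max_ratio=max_ratio,
        expressed=True,
        bin=classify_ratio(max_ratio),
        best_site=t.sites[best],
    )


def classify_bins(presences) -> dict[str, int]:
    """Count genes per presence bin; counts sum to the input size."""
    counts = {b: 0 for b in BINS}
    for p in presences:
        counts[p.bin] += 1
    return counts


def build_pt50(presences, threshold: float = 0.5, name: str = "PT_50") -> GeneSet:
    """Expressed genes whose maximal ratio reaches ``threshold``.

    With the default 0.5 this is the union of the mid and high bins: the
    genes estimated to carry at least one binding site in more than half
    of their expressed mRNA molecules.
    """
    members = [
        p.gene_id
        for p in presences
        if p.expressed and p.max_ratio is not None and p.max_ratio >= threshold
    ]
    return GeneSet(name, members)


# --- canonical seed-site scanning (convenience for toy/synthetic input) ---

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def _revcomp_dna(rna_or_dna: str) -> str:
    """Reverse complement, returned in DNA alphabet."""
    return rna_or_dna.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    """UTR-relative seed match. ``start``/``end`` half-open, 0-based."""

    start: int
    end: int
    kind: str  # 8mer, 7mer-m8, 7mer-A1


def scan_seed_sites(utr_sequence: str, mirna_sequence: str) -> list[SeedSite]:
    """Canonical miRNA seed matches (8mer, 7mer-m8, 7mer-A1) in a 3'-UTR.

    The match core is the reverse complement of miRNA positions 2-7; an
    additional match to position 8 (m8) and/or an adenosine opposite
    position 1 (A1) upgrades the site. Per matched core the single best
    type is reported (8mer > 7mer-m8 > 7mer-A1); plain 6mers are not
    reported. Coordinates are UTR-relative and cover the matched
    nucleotides including the A1 position where applicable.
    """
    utr = utr_sequence.upper().replace("U", "T")
    mirna = mirna_sequence.upper().replace("T", "U")
    for label, seq, alphabet in (("UTR", utr, set("ACGT")), ("miRNA", mirna, set("ACGU"))):
        bad = set(seq) - alphabet
        if bad:
            raise InputError(f"{label} sequence has invalid characters: {sorted(bad)}")
    if len(mirna) < 8:
        raise InputError("miRNA sequence must be at least 8 nt")

    core6 = _revcomp_dna(mirna[1:7])   # matches positions 2-7
    m8 = _revcomp_dna(mirna[7])        # nucleotide pairing position 8
    out: list[SeedSite] = []
    for i in range(len(utr) - 6 + 1):
        if utr[i : i + 6] != core6:
            continue
        has_m8 = i >= 1 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            out.append(SeedSite(i - 1, i + 7, "8mer"))
        elif has_m8:
            out.append(SeedSite(i - 1, i + 6, "7mer-m8"))
        elif has_a1:
            out.append(SeedSite(i, i + 7, "7mer-A1"))
    return sorted(out, key=lambda s: (s.start, s.end))
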