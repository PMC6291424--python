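"""Readers and writers for the standard formats the pipeline touches.

GTF/GFF3 (exon / three_prime_utr features, parsed with gffutils), BED6
binding sites, 4-column bedGraph coverage, GMT gene sets, RNK ranked
lists, TSV expression matrices with a sample sheet, and plain FASTA.
All genomic coordinates are converted to 0-based half-open on read.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .types import (
    CoverageTrack,
    FormatError,
    GeneSet,
    GenomicInterval,
    InputError,
    RankedList,
    SitePresence,
)

_UTR_FEATURES = {"three_prime_utr", "3utr", "three_prime_UTR".lower()}


@dataclass
class RawTranscript:
    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    utr_parts: list[GenomicInterval]

    def utr_span(self) -> GenomicInterval | None:
        """Union span of the annotated 3'-UTR parts (single interval model)."""
        if not self.utr_parts:
            return None
        chrom = self.utr_parts[0].chrom
        strand = self.utr_parts[0].strand
        return GenomicInterval(
            chrom,
            min(p.start for p in self.utr_parts),
            max(p.end for p in self.utr_parts),
            strand,
        )


def _attr_first(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                # GFF3 Parent values may carry a "transcript:" prefix
                return vals[0].split(":")[-1]
    return None


def read_annotation(path: str) -> list[RawTranscript]:
    """Parse exon and three_prime_utr features from a GTF/GFF3 file.

    A ``.tsv`` path instead selects the simple tab dialect with header
    columns gene_id, transcript_id, chrom, start, end, strand, feature
    (0-based half-open coordinates).
    """
    if path.endswith(".tsv"):
        return _read_annotation_tsv(path)
    found: dict[str, RawTranscript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise FormatError(
                    "expected 9 tab-separated GTF/GFF3 fields", path, lineno
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted parse errors
                raise FormatError(f"unparseable feature line: {exc}", path, lineno)
            ftype = feat.featuretype.lower()
            if ftype != "exon" and ftype not in _UTR_FEATURES:
                continue
            tid = _attr_first(feat, "transcript_id", "Parent")
            gid = _attr_first(feat, "gene_id", "gene") or tid
            if tid is None:
                raise FormatError(
                    "feature lacks transcript_id/Parent attribute", path, lineno
                )
            iv = GenomicInterval(
                feat.seqid, feat.start - 1, feat.end, feat.strand or "."
            )
            raw = found.setdefault(tid, RawTranscript(gid, tid, [], []))
            (raw.exons if ftype == "exon" else raw.utr_parts).append(iv)
    return list(found.values())


def _read_annotation_tsv(path: str) -> list[RawTranscript]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "transcript_id", "chrom", "start", "end", "strand", "feature"}
    if not required <= set(df.columns):
        raise FormatError(
            f"TSV annotation needs columns {sorted(required)}", path
        )
    found: dict[str, RawTranscript] = {}
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand))
        raw = found.setdefault(
            row.transcript_id, RawTranscript(row.gene_id, row.transcript_id, [], [])
        )
        ftype = str(row.feature).lower()
        if ftype == "exon":
            raw.exons.append(iv)
        elif ftype in _UTR_FEATURES:
            raw.utr_parts.append(iv)
    return list(found.values())


def read_bed_sites(path: str) -> list[GenomicInterval]:
    """Read binding-site intervals from a BED (>= 3 column) file."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("BED line has fewer than 3 fields", path, lineno)
            try:
                strand = fields[5] if len(fields) >= 6 else "."
                sites.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, InputError) as exc:
                raise FormatError(f"bad BED interval: {exc}", path, lineno)
    return sites


def read_bedgraph(path: str) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a dense track."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError("bedGraph line has fewer than 4 fields", path, lineno)
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"bad bedGraph line: {exc}", path, lineno)
            if value < 0:
                raise FormatError("negative coverage value", path, lineno)
            spans.setdefault(fields[0], []).append((start, end, value))
    track = CoverageTrack()
    for chrom, rows in spans.items():
        size = max(end for _, end, _ in rows)
        arr = np.zeros(size, dtype=float)
        for start, end, value in rows:
            arr[start:end] = value
        track.set_chrom(chrom, arr)
    return track


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a track as run-length-compressed bedGraph, omitting zero runs."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.depths(GenomicInterval(chrom, 0, max(1, _chrom_size(track, chrom))))
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _chrom_size(track: CoverageTrack, chrom: str) -> int:
    return track._arrays[chrom].size  # noqa: SLF001 - package-internal


def read_gmt(path: str) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("GMT line needs name, description, members", path, lineno)
            members = [g for g in fields[2:] if g]
            sets.append(GeneSet(fields[0], members))
    return sets


def write_gmt(sets, path: str, description: str = "utrpresence") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.members)]) + "\n")


def read_rnk(path: str) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene", "score"])
    return RankedList.from_unsorted(df["gene"].astype(str).to_list(), df["score"].to_list())


def write_rnk(ranked: RankedList, path: str) -> None:
    pd.DataFrame({"gene": ranked.genes, "score": ranked.scores}).to_csv(
        path, sep="\t", header=False, index=False
    )


def presence_table(presences) -> pd.DataFrame:
    """Tabulate SitePresence records (the `presence.tsv` report)."""
    rows = []
    for p in presences:
        rows.append(
            {
                "gene_id": p.gene_id,
                "median_exon_depth": p.median_exon_depth,
                "n_sites": len(p.site_ratios),
                "max_ratio": np.nan if p.max_ratio is None else p.max_ratio,
                "expressed": p.expressed,
                "bin": p.bin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "median_exon_depth", "n_sites", "max_ratio", "expressed", "bin"],
    )


def write_presence_table(presences, path: str) -> None:
    presence_table(presences).to_csv(path, sep="\t", index=False)


def read_presence_table(path: str) -> list[SitePresence]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        expressed = bool(row.expressed)
        max_ratio = None if not expressed else float(row.max_ratio)
        out.append(
            SitePresence(
                gene_id=str(row.gene_id),
                median_exon_depth=float(row.median_exon_depth),
                site_ratios=[] if max_ratio is None else [max_ratio],
                max_ratio=max_ratio,
                expressed=expressed,
                bin=str(row.bin),
            )
        )
    return out


def read_expression(
    matrix_path: str, samplesheet_path: str, presence_path: str | None = None
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(samplesheet_path, sep="\t", index_col=0)
    presence = None
    if presence_path is not None:
        presence = pd.read_csv(presence_path, sep="\t", index_col=0).astype(bool)
    return ExpressionMatrix(values, meta, presence)


def write_expression(m: ExpressionMatrix, matrix_path: str, samplesheet_path: str,
                     presence_path: str | None = None) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    m.meta.to_csv(samplesheet_path, sep="\t", index_label="sample")
    if presence_path is not None:
        m.presence.astype(int).to_csv(presence_path, sep="\t", index_label="gene_id")


def write_fasta(records: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sha256_of(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def file_exists(path: str) -> None:
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
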