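"""Synthetic inputs for the whole pipeline.

The generators emulate the two measurements the analysis rests on:

* RNA-seq coverage of transcripts whose 3'-UTR is shortened by
  alternative polyadenylation. Each UTR has one proximal/distal switch
  point; a planted fraction ``f`` of molecules retain the distal segment
  that carries the binding sites, so the distal per-base depth is
  ``f * base_depth`` plus counting noise while exons and the proximal
  UTR sit at ``base_depth``.
* Two-arm (antagomir vs scrambled control), three-timepoint expression
  matrices in which true targets are de-repressed at the last timepoint
  with a log2 effect proportional to their site-presence ratio.

Every generator is a pure function of its spec and a seed: reruns are
bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import (
    STREAM_COVERAGE,
    STREAM_MATRIX,
    STREAM_QPCR,
    STREAM_TRANSCRIPTS,
    generator,
)
from .expression import ARM_ANTAGOMIR, ARM_CONTROL, ExpressionMatrix
from .site_presence import SeedSite, scan_seed_sites
from .types import CoverageTrack, GeneSet, GenomicInterval, InputError, TranscriptModel

# mmu-miR-31-5p; its antagomir is the full reverse complement.
MIR31 = "AGGCAAGAUGCUGGCAUAGCUG"

_COMPLEMENT = str.maketrans("ACGUT", "TGCAA")


def _revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# Binding-site region planted in synthetic UTRs: full reverse complement
# of the miRNA with the nucleotide opposite position 1 forced to A, which
# makes the seed portion a canonical 8mer site.
SITE_REGION = _revcomp_dna(MIR31)[:-1] + "A"
SITE_LENGTH = len(SITE_REGION)
# Seed-match coordinates within the region (8mer: m8 + seed + A1).
SEED_OFFSET = SITE_LENGTH - 8

CHROM = "chrSim"


@dataclass
class SyntheticSpec:
    """Study conditions for the generators.

    Defaults mirror the analysed experiment: 421 putative target genes,
    two antagomir arms sampled 36/48/72 h after activation, de-repression
    of one log2 unit at 72 h scaled by each gene's site-presence ratio,
    and Poisson counting noise on a mean exonic depth of 200x.
    """

    n_genes: int = 421
    exon_count: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (100, 400)
    utr_length: tuple[int, int] = (300, 800)
    base_depth: float = 200.0
    retention: float | np.ndarray = 0.7
    noise: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 0.1
    n_samples: int = 3  # replicates per arm per timepoint
    timepoints: tuple[int, ...] = (36, 48, 72)
    effect_size: float = 1.0  # log2 units at the last timepoint
    noise_sd: float = 0.25  # log2 residual sd of the expression matrix
    background_genes: int = 579
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.retention, dtype=float))
        if np.any(f < 0) or np.any(f > 1):
            raise InputError("retention fractions must lie in [0, 1]")
        if self.effect_size < 0:
            raise InputError("effect size must be >= 0")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be > 0")
        if self.base_depth <= 0:
            raise InputError("base_depth must be > 0")
        if self.noise not in ("poisson", "negative_binomial"):
            raise InputError(f"unknown noise model {self.noise!r}")
        for name in ("exon_count", "exon_length", "intron_length", "utr_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise InputError(f"infeasible range for {name}: ({lo}, {hi})")
        if self.utr_length[0] < 8 * SITE_LENGTH:
            raise InputError(
                f"minimum UTR length must be >= {8 * SITE_LENGTH} to hold a distal site"
            )

    def retention_per_gene(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.retention, dtype=float))
        if f.size == 1:
            return np.full(self.n_genes, float(f[0]))
        if f.size != self.n_genes:
            raise InputError("retention vector length must equal n_genes")
        return f.astype(float)


@dataclass
class SimulatedGene:
    model: TranscriptModel
    utr_sequence: str
    switch: int  # genomic position of the proximal/distal switch
    planted_sites: list[SeedSite]  # UTR-relative seed matches


@dataclass
class SimulatedTranscripts:
    genes: list[SimulatedGene]
    chrom_size: int

    @property
    def models(self) -> list[TranscriptModel]:
        return [g.model for g in self.genes]

    def utr_fasta(self) -> dict[str, str]:
        return {g.model.gene_id: g.utr_sequence for g in self.genes}


def _rand_int(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def simulate_transcripts(spec: SyntheticSpec, seed: int | None = None) -> SimulatedTranscripts:
    """Non-overlapping gene loci on one synthetic chromosome.

    Each gene gets 3-6 exons, a 3'-UTR downstream of the last exon with a
    single polyadenylation switch point at 30-60% of the UTR, and one
    planted binding-site region entirely inside the distal segment. The
    seed portion of every planted region is a canonical 8mer match for
    the scanner.
    """
    rng = generator(spec.seed if seed is None else seed, STREAM_TRANSCRIPTS)
    cursor = 100
    genes: list[SimulatedGene] = []
    bases = np.array(list("ACGT"))
    for i in range(spec.n_genes):
        gene_id = f"PT{i + 1:04d}"
        n_exons = _rand_int(rng, spec.exon_count)
        exons = []
        for _ in range(n_exons):
            length = _rand_int(rng, spec.exon_length)
            exons.append(GenomicInterval(CHROM, cursor, cursor + length, "+"))
            cursor += length + _rand_int(rng, spec.intron_length)
        utr_len = _rand_int(rng, spec.utr_length)
        utr_start = exons[-1].end
        utr = GenomicInterval(CHROM, utr_start, utr_start + utr_len, "+")
        # switch point: proximal molecules end here, distal ones read through
        switch_rel = int(round(utr_len * rng.uniform(0.3, 0.6)))
        # place the site region inside the distal segment with margins
        lo = switch_rel + SITE_LENGTH
        hi = utr_len - 2 * SITE_LENGTH
        site_rel = int(rng.integers(lo, hi + 1))
        site = GenomicInterval(CHROM, utr_start + site_rel, utr_start + site_rel + SITE_LENGTH, "+")

        seq = rng.choice(bases, size=utr_len)
        seq[site_rel : site_rel + SITE_LENGTH] = list(SITE_REGION)
        utr_sequence = "".join(seq)
        planted = [
            SeedSite(site_rel + SEED_OFFSET, site_rel + SEED_OFFSET + 8, "8mer")
        ]
        model = TranscriptModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            exons=exons,
            utr3=utr,
            sites=[site],
        )
        genes.append(
            SimulatedGene(model, utr_sequence, utr_start + switch_rel, planted)
        )
        cursor = utr.end + 200
    return SimulatedTranscripts(genes, cursor)


def _noise_depths(rng: np.random.Generator, mean: float, n: int, spec: SyntheticSpec) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n)
    if spec.noise == "poisson":
        return rng.poisson(mean, size=n).astype(float)
    shape = 1.0 / spec.nb_dispersion
    lam = rng.gamma(shape, mean / shape, size=n)
    return rng.poisson(lam).astype(float)


def simulate_coverage(
    sim: SimulatedTranscripts,
    spec: SyntheticSpec,
    seed: int | None = None,
    depths: np.ndarray | None = None,
    exact: bool = False,
) -> CoverageTrack:
    """Coverage with planted distal-UTR retention.

    Exons and the proximal UTR segment are covered at the per-gene depth;
    the distal segment downstream of the switch point (which contains the
    binding sites) at ``f * depth``. ``exact`` replaces counting noise by
    the exact means (used by the packaged fixture so planted ratios are
    reproduced bit-exactly).
    """
    rng = generator(spec.seed if seed is None else seed, STREAM_COVERAGE)
    f = spec.retention_per_gene()
    if depths is None:
        depths = np.full(spec.n_genes, spec.base_depth)
    arr = np.zeros(sim.chrom_size, dtype=float)

    def fill(iv: GenomicInterval, mean: float) -> None:
        if exact:
            arr[iv.start : iv.end] = mean
        else:
            arr[iv.start : iv.end] = _noise_depths(rng, mean, len(iv), spec)

    for g, fg, d in zip(sim.genes, f, depths):
        for exon in g.model.exons:
            fill(exon, d)
        utr = g.model.utr3
        fill(GenomicInterval(CHROM, utr.start, max(utr.start + 1, g.switch)), d)
        if g.switch < utr.end:
            fill(GenomicInterval(CHROM, g.switch, utr.end), fg * d)
    return CoverageTrack({CHROM: arr})


# Bin targets of the packaged fixture: high / mid / low / not detected.
REFERENCE_BIN_COUNTS = (134, 72, 76, 139)
REFERENCE_DEPTH = 200.0
# Planted-ratio windows keep every gene >= 0.05 away from the 0.5 / 0.9
# bin boundaries so recomputation cannot drift across a cutpoint.
_REFERENCE_WINDOWS = ((0.95, 1.15), (0.55, 0.85), (0.05, 0.45))


def make_reference_fixture(
    seed: int = 0,
) -> tuple[SimulatedTranscripts, CoverageTrack, GeneSet]:
    """The packaged 421-gene putative-target fixture.

    134 genes carry planted presence ratios above 0.9, 72 in [0.5, 0.9],
    76 below 0.5, and 139 have zero coverage (transcript not detectable).
    Ratios are planted exactly (noise-free coverage at 200x), so the
    presence pipeline reproduces the four bin counts, the 282 expressed
    genes and the 206-gene PT_50 set exactly.
    """
    n_high, n_mid, n_low, n_nd = REFERENCE_BIN_COUNTS
    n_genes = sum(REFERENCE_BIN_COUNTS)
    rng = generator(seed, STREAM_TRANSCRIPTS, 1)
    fs = np.concatenate(
        [
            rng.uniform(lo, hi, size=n)
            for (lo, hi), n in zip(_REFERENCE_WINDOWS, (n_high, n_mid, n_low))
        ]
        + [np.zeros(n_nd)]
    )
    depths = np.concatenate(
        [np.full(n_high + n_mid + n_low, REFERENCE_DEPTH), np.zeros(n_nd)]
    )
    spec = SyntheticSpec(n_genes=n_genes, retention=np.minimum(fs, 1.0), seed=seed)
    sim = simulate_transcripts(spec, seed)
    # plant the (possibly > 1) target ratios directly as distal depths
    cov = simulate_coverage(
        sim,
        SyntheticSpec(n_genes=n_genes, retention=np.ones(n_genes), seed=seed),
        seed,
        depths=depths,
        exact=True,
    )
    arr = cov.depths(GenomicInterval(CHROM, 0, sim.chrom_size))
    for g, f, d in zip(sim.genes, fs, depths):
        if d > 0:
            arr[g.switch : g.model.utr3.end] = f * d
    roster = GeneSet("PT", [g.model.gene_id for g in sim.genes])
    return sim, CoverageTrack({CHROM: arr}), roster


def simulate_knockdown_matrix(
    pt_presence,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Antagomir-vs-control expression matrix with planted de-repression.

    Every gene draws a log2 baseline; antagomir-arm samples at the last
    timepoint add ``effect_size * w_g`` to putative targets, where
    ``w_g = min(max_ratio, 1)`` is the gene's site-presence weight (0 for
    undetectable transcripts). Earlier timepoints carry no effect, which
    reproduces the late de-repression kinetics of antagomir knock-down.
    Background genes pad the ranked universe.
    """
    if spec.effect_size > 0 and 72 not in spec.timepoints:
        raise InputError("effect_size > 0 requires the 72 h timepoint")
    rng = generator(spec.seed if seed is None else seed, STREAM_MATRIX)
    pt_genes = [p.gene_id for p in pt_presence]
    weights = np.array(
        [
            min(p.max_ratio, 1.0) if (p.expressed and p.max_ratio is not None) else 0.0
            for p in pt_presence
        ]
    )
    genes = pt_genes + [f"BG{i + 1:04d}" for i in range(spec.background_genes)]
    w = np.concatenate([weights, np.zeros(spec.background_genes)])

    samples, arms, tps, reps = [], [], [], []
    for arm in (ARM_ANTAGOMIR, ARM_CONTROL):
        for tp in spec.timepoints:
            for rep in range(1, spec.n_samples + 1):
                samples.append(f"{arm}_{tp}h_r{rep}")
                arms.append(arm)
                tps.append(tp)
                reps.append(rep)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(genes), len(samples)))
    effect_cols = np.array(
        [(a == ARM_ANTAGOMIR) and (t == 72) for a, t in zip(arms, tps)]
    )
    values[:, effect_cols] += spec.effect_size * w[:, None]

    meta = pd.DataFrame(
        {"arm": arms, "timepoint": tps, "replicate": reps}, index=samples
    )
    vdf = pd.DataFrame(values, index=genes, columns=samples)
    presence = pd.DataFrame(True, index=genes, columns=samples)
    if spec.dropout_rate > 0:
        presence &= rng.random(presence.shape) >= spec.dropout_rate
    return ExpressionMatrix(vdf, meta, presence)


def simulate_qpcr(
    planted_relative_expression: float,
    n_replicates: int,
    seed: int = 0,
    group: str = "treated",
) -> pd.DataFrame:
    """Toy qPCR CT table around a planted relative expression.

    Reference CT ~ Normal(20, 0.2); target CT = reference
    - log2(planted) + Normal(0, 0.1), so 2^-dCT recovers the planted
    value in expectation.
    """
    if planted_relative_expression <= 0:
        raise InputError("planted relative expression must be > 0")
    rng = generator(seed, STREAM_QPCR)
    reference = rng.normal(20.0, 0.2, size=n_replicates)
    target = reference - np.log2(planted_relative_expression) + rng.normal(
        0.0, 0.1, size=n_replicates
    )
    return pd.DataFrame(
        {
            "sample": [f"{group}_r{i + 1}" for i in range(n_replicates)],
            "target_ct": target,
            "reference_ct": reference,
            "group": group,
        }
    )
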