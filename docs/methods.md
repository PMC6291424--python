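# Methods

## The measurement problem

miRNA target prediction from sequence conservation produces many false
positives in any particular cell state. One underappreciated reason is
3′-UTR shortening: activated, proliferating T helper cells switch to
proximal polyadenylation sites, producing transcripts that physically
lack distal 3′-UTR sequence and any miRNA binding sites located there. A
predicted target whose site sits downstream of the poly(A) switch point
cannot respond to the miRNA, however good the prediction. `utrpresence`
quantifies site *presence* directly from total RNA-seq coverage and
carries that information through enrichment testing of a knock-down
experiment.

## Site-presence ratio

For a transcript with exon intervals E and a binding-site interval S in
the 3′-UTR:

```
r = mean(coverage over S) / median(per-base coverage pooled over E)
```

Under a two-isoform (proximal/distal) mixture in which a fraction *f* of
molecules read through the switch point, the expected coverage downstream
of the switch is *f* times the exonic depth, so *r* estimates *f* — the
fraction of expressed molecules carrying the site. Choices:

* **Denominator** — the *median* of per-base exon depths is robust to
  coverage spikes and 3′ bias within exons.
* **Numerator** — the arithmetic *mean* over the site window (7–22 nt;
  windows this short make a median both grainy and noisier); a median
  aggregator and symmetric flank padding (default 0) are config options.
* **Multiple sites** — the maximal ratio over sites is reported (a gene
  responds through its best-retained site); ties resolve to the first
  site in genomic order.
* **Detectability** — a gene is `expressed` when its median exon depth
  reaches `min_expressed_depth` (default 1.0×, i.e. at least half the
  exonic bases covered); otherwise the ratio is undefined and the gene
  is reported `not_detected`. The threshold is deliberately minimal —
  "no detectable transcript" — and configurable.
* **Bins** — high: *r* > 0.9 (strictly), mid: 0.5 ≤ *r* ≤ 0.9, low:
  *r* < 0.5. Ratios are not capped: sampling noise can push *r* slightly
  above 1 and such genes belong in the high bin. PT₅₀ = expressed genes
  with *r* ≥ 0.5, so PT₅₀ = mid ∪ high.
* **Coordinates** — 0-based half-open everywhere; GTF/GFF3 input is
  converted on read. Coverage is treated as unstranded (total RNA-seq).
* **Isoforms** — when a gene has several annotated transcripts the one
  with the longest 3′-UTR is used (deterministic, maximizes site
  capture); ties break to the lexicographically smallest transcript id.
  Multi-part UTR annotations are collapsed to their genomic span.

Scale invariance: multiplying a coverage track by c > 0 leaves every
ratio unchanged (only the expressed flag can change), so library size
does not matter to *r*.

## Seed-site scanner

A convenience scanner finds canonical seed matches of a miRNA in a UTR
sequence: the reverse complement of miRNA positions 2–7 (6mer core),
upgraded by a match to position 8 (m8) and/or an adenosine opposite
position 1 (A1): 8mer (m8 + core + A1), 7mer-m8, 7mer-A1. One best site
per core match is reported; bare 6mers are not. It exists so toy and
synthetic inputs can be built without an external prediction tool; real
analyses consume predicted site coordinates (BED).

## Enrichment engine

Genes are ranked by a two-class metric — default signal-to-noise
(μ₁−μ₂)/(σ₁+σ₂) with each σ floored at max(σ, 0.2·|μ|) (0.2 if μ = 0) to
stabilise low-replicate arrays; log2 ratio of means and difference of
means are alternatives. The positive class is the antagomir arm, so
positive scores mean de-repression after miRNA knock-down. Ties break by
gene id, making ranks deterministic.

The running enrichment score walks the ranked list, adding
|score|^weight (normalized over the set's members) at members and
subtracting 1/(N−k) at non-members; ES is the signed extremum (earliest
rank at ties). Weight 1 is the default; weight 0 reduces to the
classical Kolmogorov–Smirnov-type statistic, which the test suite checks
against an exhaustive independent walk for every membership pattern up
to list length 12. If all member scores are exactly 0 (degenerate under
weight > 0) the walk falls back to uniform increments.

The permutation null draws random same-size gene sets from the ranked
universe (`gene_set` mode, default — with two arms and few replicates,
phenotype permutation has too few distinct relabelings; `phenotype` mode
with label permutation and re-ranking is available). NES = ES divided by
the mean |null ES| of the same sign; nominal p uses the add-one rule
(1 + #{same-sign |null| ≥ |ES|}) / (1 + #same-sign), so p is never 0.
Random set sizes of N−1 are rejected as degenerate (the null would have
at most N atoms). Set members absent from the ranked list are dropped
with a logged count. Null ES values are computed as one vectorized
cumulative sum over a permutations × genes matrix, which is what makes
the resampling procedure below affordable at thousands of GSEAs.

Under exchangeable null data the nominal p of a fixed gene set is
uniform; this is verified by simulation (KS test over 200 replicates,
and a 1000-replicate check during development).

## Random-subset resampling significance

The question: is PT₅₀ more enriched than a random subset of PT of the
same size would be? The procedure runs B (default 1000) independent
GSEAs, each on a uniformly drawn size-|PT₅₀| subset of PT with its own
derived permutation seed, collecting their NES values as the null
sample. The "observed" sample is R (default 20) NES replicates of PT₅₀
itself under independent permutation seeds — PT₅₀'s ES on a fixed ranked
list is deterministic, so these replicates vary only through the
estimated normalization constant. Welch's unequal-variance t test
compares the two samples; a two-sample test needs ≥ 2 observations per
side, which is exactly what the R replicates provide.

**Calibration caveat (important).** The Welch p answers a *conditional*
question — "given this ranked list, does PT₅₀'s NES differ from the mean
NES of random same-size PT subsets?" — and its denominator shrinks with
1/R + 1/B while PT₅₀'s NES never averages over subset draws. As a test
of the *global* null ("PT₅₀ is exchangeable with a random PT subset") it
is therefore strongly anti-conservative: simulations in this package
show welch_p ≤ 0.05 in ~95% of null datasets at B = 200, R = 20. For a
calibrated global-null summary the outcome also reports the empirical
percentile of the mean observed NES within the null sample and the
add-one empirical p, (1 + #{null ≥ observed}) / (1 + B), which is
uniform under exchangeability (verified by KS test) and has monotone
power in the planted effect size. Report the Welch statistic for
comparability, the empirical p for inference.

All randomness flows from one top-level seed through named substreams
(SeedSequence spawn keys indexed by a CRC of the stream name plus a
counter), so outcomes are bit-identical across reruns and independent of
evaluation order.

## Expression preparation and small statistics

* **Expressed-gene filter**: keep a gene if it is called present in
  ≥ 50% of the antagomir arm's samples OR ≥ 50% of the control arm's
  samples. By default samples pool across timepoints within an arm (one
  filter for the experiment); a per-timepoint mode keeps a gene passing
  in any single timepoint. The filter consumes upstream detection calls
  (e.g. MAS5 present/absent); normalization itself is out of scope.
* **qPCR**: relative expression 2^−ΔCT with ΔCT = target CT − reference
  CT; shift-invariant in the common cycle offset. Fold change vs.
  control uses arithmetic means of relative expressions (matching
  mean ± SEM reporting); a geometric-mean mode is available.
* **Mann–Whitney U**, two-sided: exact null distribution when both
  samples have ≤ 8 observations and no ties, otherwise the tie-corrected
  normal approximation; the exact branch is checked against a full
  enumeration oracle.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions used throughout the tests:

* **Transcript models**: 421 putative-target genes (plus background) on
  one synthetic chromosome; 3–6 exons of 100–300 nt, introns 100–400 nt,
  3′-UTRs 300–800 nt with a single poly(A) switch point at 30–60% of the
  UTR; one 22-nt binding-site region per UTR entirely downstream of the
  switch, whose seed portion is a canonical 8mer for the bundled miR-31
  sequence.
* **Coverage**: per-base Poisson counts (negative binomial with
  dispersion 0.1 optional) around depth 200× on exons and the proximal
  UTR, and f·200× downstream of the switch — the minimal two-isoform
  model the ratio statistic is designed to detect.
* **Reference fixture**: 421 genes whose ratios are planted *exactly*
  (noise-free coverage) inside windows keeping ≥ 0.05 margin from the
  0.5/0.9 cutpoints — 134 high, 72 mid, 76 low — plus 139 genes with
  zero coverage; the presence pipeline reproduces 134/72/76/139, 282
  expressed and |PT₅₀| = 206 exactly, for any seed.
* **Knock-down matrices**: two arms (antagomir / scrambled control) ×
  timepoints 36/48/72 h × 3 replicates; log2 baselines N(7, 1), residual
  sd 0.25; antagomir samples at 72 h only add δ·min(r, 1) to putative
  targets (default δ = 1 log2 unit), reproducing late de-repression
  kinetics, with presence-proportional effects; 579 background genes pad
  the ranked universe to 1000. Replicate count and background size are
  package choices typical of small two-colour-free array designs.
* **qPCR tables**: reference CT ~ N(20, 0.2), target CT = reference −
  log2(planted) + N(0, 0.1).

Not modelled: fragment-level read simulation, GC/positional coverage
bias, probe effects, correlated gene-gene noise, partial UTR isoform
mixtures beyond one switch point, and real miRNA dose-response. Passing
tests therefore demonstrate correctness of the statistics and recovery
of planted signals under idealized counting noise — not performance on
real libraries with structured bias.

## Numerical and degenerate-input conventions

Empty coverage yields median depth 0 → `not_detected`. An expressed gene
with no annotated site gets ratio 0 (low bin). ES ties take the earliest
extremum; an observed ES of 0 maps to NES 0, p 1; an ES whose sign no
null shares raises an explicit error rather than returning a fabricated
NES. Welch's test refuses samples with < 2 observations or zero variance
in both (equal-constant samples return t = 0, p = 1). Mann–Whitney p is
capped at 1. The presence filter requires both arms to have samples.

## Problem sizes in the test suite

Stochastic checks run at reduced scale as package defaults: resampling
calibration 200 replicates at B = 200, R = 20, 100 permutations per
GSEA; power 50 runs at δ = 1; timepoint specificity 200 simulations at
200 permutations; ratio recovery 9 retention levels × 200 replicates at
depth 200×. The full-scale defaults (B = 1000, 1000 permutations) remain
the library defaults.

## Known limitations

* The Welch construction is reported for continuity but is not a
  calibrated global-null test (see above); the empirical p is.
* The ratio statistic assumes all annotated sites lie downstream of a
  single switch point; a site upstream of every used poly(A) site will
  show r ≈ 1 regardless of shortening elsewhere.
* Unstranded coverage conflates overlapping antisense transcription
  into both numerator and denominator.
* The isoform rule (longest 3′-UTR) can overstate site presence for
  genes whose dominant isoform uses a shorter UTR annotation.
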