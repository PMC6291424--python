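# utrpresence

Identify which predicted miRNA target genes still *physically carry* their
binding site in a given cell state — and test whether those genes respond
more strongly to miRNA inhibition.

Activated, proliferating T helper cells shorten their 3′ untranslated
regions (3′-UTRs) through alternative polyadenylation. A binding site that
a prediction tool places in the distal 3′-UTR may therefore be absent from
most of the mRNA molecules the cell actually expresses, and the gene will
not respond to perturbations of the miRNA. `utrpresence` implements a
coverage-based workflow that accounts for this:

1. **Site-presence ratio.** For each gene with a predicted binding site,
   compute from total RNA-seq coverage

   *r* = (mean coverage of the binding-site region in the 3′-UTR) /
   (median per-base coverage of the transcript's exons),

   an estimate of the fraction of expressed mRNA molecules that retain the
   site. With several sites the maximal ratio is kept. Genes are binned at
   *r* > 0.9 (high), 0.5 ≤ *r* ≤ 0.9 (mid), *r* < 0.5 (low); genes without
   detectable transcript are reported separately.
2. **PT₅₀ set.** From a universe of putative targets (PT), the subset with
   *r* ≥ 0.5 among expressed genes — genes carrying the site in more than
   half of their expressed molecules — forms the PT₅₀ gene set.
3. **Enrichment after miRNA inhibition.** Gene set enrichment analysis
   (weighted running-sum enrichment score ES, permutation null,
   normalized enrichment score NES, add-one nominal *p*) of PT and PT₅₀
   in transcriptomes of antagomir-treated versus scrambled-control cells,
   per timepoint.
4. **Random-subset resampling significance.** Is PT₅₀ *more* enriched
   than a random subset of PT of the same size? B independent GSEAs on
   uniformly drawn size-|PT₅₀| subsets of PT provide the null NES sample,
   compared against replicate PT₅₀ NES values with Welch's unequal-variance
   t test, alongside the calibrated empirical percentile/p of the PT₅₀ NES
   within the null sample.

A synthetic-data module generates every input needed to exercise the whole
pipeline without downloads: coverage tracks with a planted distal-UTR
retention fraction, two-arm (antagomir vs. scrambled) three-timepoint
expression matrices with target de-repression proportional to site
presence, seed-match UTR sequences for the bundled miR-31 scanner, and toy
qPCR CT tables (2^−ΔCT normalization). Small statistics used alongside
(expressed-gene presence filter, fold change, Mann–Whitney U) are included.

Intended users: computational biologists analysing miRNA
perturbation experiments (antagomir/LNA knock-down, mimics) who have
transcript annotation, predicted site coordinates, per-base coverage and a
normalized expression matrix.

## Worked example

```python
import utrpresence as up
from utrpresence.enrichment import GseaConfig

# 421-gene putative-target reference fixture: transcript models, coverage
# with planted retention fractions, and the PT roster
sim, cov, pt = up.make_reference_fixture(seed=1)
presences = [up.site_presence(m, cov) for m in sim.models]
print(up.classify_bins(presences))
pt50 = up.build_pt50(presences)

# synthetic antagomir experiment: de-repression proportional to site
# presence, planted only at 72 h
spec = up.SyntheticSpec(effect_size=1.0, noise_sd=0.25, seed=11)
expr = up.simulate_knockdown_matrix(presences, spec)
for tp in (36, 48, 72):
    for r in up.run_gsea(expr.subset_timepoint(tp), None, [pt, pt50],
                         GseaConfig(n_perm=1000), seed=11 + tp):
        print(tp, r.set_name, round(r.nes, 3), round(r.nominal_p, 4))

out = up.pt50_significance(pt, pt50, expr.subset_timepoint(72),
                           B=200, R=20, config=GseaConfig(n_perm=200), seed=11)
```

Output:

```
bins: {'high': 134, 'mid': 72, 'low': 76, 'not_detected': 139}
expressed: 282 of 421; |PT_50| = 206
36 h  PT     ES=-0.147  NES=-0.775  p=0.9886
36 h  PT_50  ES=+0.185  NES=+0.936  p=0.6691
48 h  PT     ES=-0.159  NES=-0.816  p=0.9574
48 h  PT_50  ES=+0.175  NES=+0.860  p=0.8531
72 h  PT     ES=+0.809  NES=+2.051  p=0.0010
72 h  PT_50  ES=+0.943  NES=+2.378  p=0.0010
mean NES(PT_50) = 2.368   mean NES(random PT subsets) = 1.709
Welch t = 130.48 (df = 63.0), p = 2.1e-78
empirical p = 0.0050 (percentile 1.000)
```

Reading it: of the 421 putative targets, 282 are expressed and 206 keep
their binding site in most expressed molecules (PT₅₀). Neither gene set is
enriched at 36 or 48 h; at 72 h both are strongly enriched among genes
up-regulated after miRNA inhibition, and PT₅₀ sits far above the NES
distribution of 200 random same-size PT subsets — the planted
presence-proportional de-repression is recovered with the correct timing
and direction. (See `docs/methods.md` on why the Welch *p* overstates and
the empirical *p* is the calibrated summary.)

## Command line

```bash
utrpresence simulate --seed 5 --out-dir data/          # synthetic inputs
utrpresence presence --annotation data/annotation.tsv --sites data/sites.bed \
    --coverage data/coverage.bedgraph --out presence.tsv
utrpresence pt50 --presence presence.tsv --out pt50.gmt
utrpresence gsea --expr data/expression.tsv --meta data/samples.tsv \
    --sets pt50.gmt --timepoint 72 --seed 17 --out gsea.json
utrpresence resample --expr data/expression.tsv --meta data/samples.tsv \
    --pt pt.gmt --pt50 pt50.gmt --seed 17 --out resample.json
utrpresence pipeline --config config.yaml               # all of the above
```

File formats: GTF/GFF3 or simple TSV annotation, BED6 sites, 4-column
bedGraph coverage, GMT gene sets, RNK ranked lists, TSV matrices and
sample sheets. All coordinates are 0-based half-open internally.

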