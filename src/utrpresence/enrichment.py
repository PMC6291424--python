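"""Gene set enrichment analysis: ranking metric, weighted running-sum
enrichment score, permutation null, NES and nominal p.

The running statistic follows the standard GSEA construction: walking
down the ranked list, the sum gains |score|^weight (normalized over the
set's hits) at each set member and loses 1/(N - n_hits) at each
non-member; the enrichment score is the signed extremum of the walk.
With weight 0 this reduces to the classical Kolmogorov-Smirnov-type
statistic. NES normalizes the ES by the mean absolute null ES of the
same sign, and the nominal p-value uses an add-one correction so it is
never exactly zero.

Null ES batches are fully vectorized (one cumulative sum over a
permutations x genes matrix), which is what makes the random-subset
resampling procedure affordable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._rng import STREAM_GSEA, generator
from .expression import ARM_ANTAGOMIR, ExpressionMatrix
from .types import GeneSet, GseaResult, InputError, RankedList

log = logging.getLogger(__name__)

METRICS = ("signal_to_noise", "log2_ratio_of_means", "difference_of_means")


@dataclass
class GseaConfig:
    """Knobs of the enrichment engine.

    ``metric``: per-gene two-class statistic ordering the list.
    ``weight``: exponent on |score| in the running sum (1 = weighted GSEA,
    0 = classical KS walk).
    ``n_perm``: permutations for the null.
    ``mode``: ``gene_set`` draws random same-size gene sets; ``phenotype``
    permutes arm labels and re-ranks (needs >= 2 samples per arm).
    """

    metric: str = "signal_to_noise"
    weight: float = 1.0
    n_perm: int = 1000
    mode: str = "gene_set"
    sigma_floor_fraction: float = 0.2
    positive_class: str = ARM_ANTAGOMIR

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise InputError(f"unknown metric {self.metric!r}")
        if self.mode not in ("gene_set", "phenotype"):
            raise InputError(f"unknown permutation mode {self.mode!r}")
        if self.n_perm < 1:
            raise InputError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "weight": self.weight,
            "n_perm": self.n_perm,
            "mode": self.mode,
            "sigma_floor_fraction": self.sigma_floor_fraction,
            "positive_class": self.positive_class,
        }


def _metric_scores(
    values: np.ndarray, pos: np.ndarray, neg: np.ndarray, metric: str,
    sigma_floor_fraction: float,
) -> np.ndarray:
    a = values[:, pos]
    b = values[:, neg]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    if metric == "difference_of_means":
        return mu_a - mu_b
    if metric == "log2_ratio_of_means":
        if np.any(mu_a <= 0) or np.any(mu_b <= 0):
            raise InputError("log2_ratio_of_means needs positive class means")
        return np.log2(mu_a / mu_b)
    # signal-to-noise with the conventional sigma floor
    sd_a = a.std(axis=1, ddof=1) if a.shape[1] > 1 else np.zeros_like(mu_a)
    sd_b = b.std(axis=1, ddof=1) if b.shape[1] > 1 else np.zeros_like(mu_b)
    floor_a = sigma_floor_fraction * np.abs(mu_a)
    floor_b = sigma_floor_fraction * np.abs(mu_b)
    floor_a[floor_a == 0] = sigma_floor_fraction
    floor_b[floor_b == 0] = sigma_floor_fraction
    sd_a = np.maximum(sd_a, floor_a)
    sd_b = np.maximum(sd_b, floor_b)
    return (mu_a - mu_b) / (sd_a + sd_b)


def rank_genes(
    expr: ExpressionMatrix,
    arm_labels=None,
    metric: str = "signal_to_noise",
    positive_class: str = ARM_ANTAGOMIR,
    sigma_floor_fraction: float = 0.2,
) -> RankedList:
    """Rank genes by a two-class differential-expression metric.

    Positive scores mean higher in ``positive_class`` (by default the
    antagomir arm, i.e. de-repressed after miRNA knock-down). Ties are
    broken by lexicographic gene id.
    """
    labels = pd.Series(
        arm_labels if arm_labels is not None else expr.arm_labels()
    )
    if arm_labels is not None and len(labels) != len(expr.samples):
        raise InputError("arm_labels length must match sample count")
    labels.index = expr.samples
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise InputError(f"ranking needs exactly 2 classes, got {classes}")
    if positive_class not in classes:
        positive_class = classes[0]
    pos = (labels == positive_class).to_numpy()
    neg = ~pos
    if pos.sum() == 0 or neg.sum() == 0:
        raise InputError("each class needs >= 1 sample")
    scores = _metric_scores(
        expr.values.to_numpy(dtype=float), pos, neg, metric, sigma_floor_fraction
    )
    return RankedList.from_unsorted(list(expr.values.index), scores)


def _hit_weights(scores: np.ndarray, weight: float) -> np.ndarray:
    return np.abs(scores) ** weight if weight != 0 else np.ones_like(scores)


def _batch_es(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Enrichment scores for a batch of membership patterns.

    ``weights``: (N,) per-rank |score|^weight values of the ranked list.
    ``hits``: (M, N) boolean membership matrix; every row must contain at
    least one hit and at least one miss.
    Returns the (M,) signed extremum of each running sum; at tied
    |extrema| the earliest rank wins.
    """
    hits = np.atleast_2d(hits)
    m, n = hits.shape
    k = hits.sum(axis=1)
    if np.any(k == 0) or np.any(k == n):
        raise InputError("each set must be a non-empty proper subset of the list")
    hw = np.where(hits, weights[None, :], 0.0)
    denom = hw.sum(axis=1)
    degenerate = denom == 0  # all member scores exactly 0: fall back to KS walk
    if np.any(degenerate):
        hw[degenerate] = hits[degenerate].astype(float)
        denom[degenerate] = k[degenerate]
    inc = hw / denom[:, None] - (~hits) / (n - k)[:, None]
    cs = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(cs), axis=1)
    return cs[np.arange(m), idx]


def enrichment_score(
    ranked: RankedList, s: GeneSet, weight: float = 1.0
) -> GseaResult:
    """Running-sum enrichment of ``s`` in ``ranked`` (ES only; NES/p unset).

    Set members absent from the ranked list are dropped (their count is
    recorded on the result). The leading edge contains the members at or
    before the extremum for positive ES, and at or after it for negative
    ES.
    """
    gene_index = {g: i for i, g in enumerate(ranked.genes.tolist())}
    used = sorted(g for g in s.members if g in gene_index)
    n_dropped = len(s.members) - len(used)
    if n_dropped:
        log.info("set %s: %d members absent from the ranked list", s.name, n_dropped)
    n = len(ranked)
    if not used:
        raise InputError(f"set {s.name!r} is disjoint from the ranked list")
    if len(used) == n:
        raise InputError(f"set {s.name!r} covers the entire ranked list")
    hit_positions = np.array(sorted(gene_index[g] for g in used), dtype=int)
    hits = np.zeros(n, dtype=bool)
    hits[hit_positions] = True

    weights = _hit_weights(ranked.scores, weight)
    hw = np.where(hits, weights, 0.0)
    denom = hw.sum()
    if denom == 0:
        hw = hits.astype(float)
        denom = hits.sum()
    inc = hw / denom - (~hits) / (n - hits.sum())
    running = np.cumsum(inc)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        le_positions = hit_positions[hit_positions <= peak]
    else:
        le_positions = hit_positions[hit_positions > peak]
    leading_edge = [str(ranked.genes[i]) for i in le_positions]
    return GseaResult(
        set_name=s.name,
        es=es,
        running_scores=running,
        hit_positions=hit_positions,
        leading_edge=leading_edge,
        n_members_used=len(used),
        n_members_dropped=n_dropped,
    )


def _gene_set_null(
    ranked: RankedList, k: int, n_perm: int, weight: float, rng: np.random.Generator,
    chunk: int = 4096,
) -> np.ndarray:
    """Null ES from ``n_perm`` random size-``k`` gene sets."""
    n = len(ranked)
    if not 0 < k < n:
        raise InputError("random set size must be a non-empty proper subset")
    if k > n - 2:
        # size N-1 sets are determined by the single excluded gene: the
        # null has at most N atoms and is useless as a reference
        raise InputError(f"random set size {k} is degenerate for a list of {n}")
    weights = _hit_weights(ranked.scores, weight)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        u = rng.random((m, n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        hits = np.zeros((m, n), dtype=bool)
        hits[np.repeat(np.arange(m), k), idx.ravel()] = True
        out[done : done + m] = _batch_es(weights, hits)
        done += m
    return out


def permutation_null(
    expr: ExpressionMatrix,
    arm_labels,
    s: GeneSet,
    n_perm: int,
    mode: str = "gene_set",
    seed: int = 0,
    config: GseaConfig | None = None,
) -> np.ndarray:
    """Null enrichment scores for ``s``.

    ``gene_set`` mode keeps the ranked list fixed and draws random gene
    sets of the same effective size; ``phenotype`` mode permutes the arm
    labels and re-ranks for every permutation.
    """
    cfg = config or GseaConfig()
    cfg = replace(cfg, n_perm=n_perm, mode=mode)
    ranked = rank_genes(expr, arm_labels, cfg.metric, cfg.positive_class,
                        cfg.sigma_floor_fraction)
    rng = generator(seed, STREAM_GSEA, 0)
    return _null_for_ranked(ranked, s, cfg, rng, expr, arm_labels)


def _null_for_ranked(
    ranked: RankedList,
    s: GeneSet,
    cfg: GseaConfig,
    rng: np.random.Generator,
    expr: ExpressionMatrix | None = None,
    arm_labels=None,
) -> np.ndarray:
    present = frozenset(ranked.genes.tolist())
    k = len(s.members & present)
    if cfg.mode == "gene_set":
        return _gene_set_null(ranked, k, cfg.n_perm, cfg.weight, rng)
    if expr is None:
        raise InputError("phenotype mode needs the expression matrix")
    labels = pd.Series(arm_labels if arm_labels is not None else expr.arm_labels())
    counts = labels.value_counts()
    if (counts < 2).any():
        raise InputError("phenotype mode needs >= 2 samples per class")
    out = np.empty(cfg.n_perm)
    lab = labels.to_numpy()
    for i in range(cfg.n_perm):
        perm = rng.permutation(lab)
        r = rank_genes(expr, perm, cfg.metric, cfg.positive_class,
                       cfg.sigma_floor_fraction)
        out[i] = enrichment_score(r, s, cfg.weight).es
    return out


def normalize_and_p(observed_es: float, null_es) -> tuple[float, float]:
    """NES and add-one nominal p against same-sign null scores.

    NES = ES / mean(|null ES|) over nulls sharing the sign of ES;
    p = (1 + #{same-sign |null| >= |ES|}) / (1 + #same-sign). An observed
    ES whose sign no null score shares has an undefined NES (raises).
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise InputError("need at least one null enrichment score")
    if observed_es == 0:
        return 0.0, 1.0
    same = null_es > 0 if observed_es > 0 else null_es < 0
    n_same = int(same.sum())
    if n_same == 0:
        raise InputError("no null ES shares the sign of the observed ES; NES undefined")
    mean_abs = float(np.abs(null_es[same]).mean())
    nes = float(observed_es / mean_abs)
    n_ge = int((np.abs(null_es[same]) >= abs(observed_es)).sum())
    p = (1 + n_ge) / (1 + n_same)
    return nes, float(p)


def run_gsea(
    expr: ExpressionMatrix,
    arm_labels=None,
    sets: list[GeneSet] = (),
    config: GseaConfig | None = None,
    seed: int = 0,
) -> list[GseaResult]:
    """One GseaResult (ES, NES, nominal p, leading edge) per gene set.

    All sets are scored against the same ranked list; the permutation
    stream for set *i* derives from ``seed`` and *i*, so results do not
    depend on the order the sets are given in.
    """
    cfg = config or GseaConfig()
    if not sets:
        return []
    ranked = rank_genes(expr, arm_labels, cfg.metric, cfg.positive_class,
                        cfg.sigma_floor_fraction)
    results = []
    for i, s in enumerate(sorted(sets, key=lambda x: x.name)):
        res = enrichment_score(ranked, s, cfg.weight)
        rng = generator(seed, STREAM_GSEA, i)
        null = _null_for_ranked(ranked, s, cfg, rng, expr, arm_labels)
        res.nes, res.nominal_p = normalize_and_p(res.es, null)
        results.append(res)
    return results


def positive_correlation_genes(
    result: GseaResult, ranked: RankedList, name: str | None = None
) -> GeneSet:
    """Set members with a strictly positive rank metric score.

    These are the genes de-repressed after miRNA knock-down that drive a
    positive enrichment score.
    """
    members = [
        str(ranked.genes[i])
        for i in result.hit_positions
        if ranked.scores[i] > 0
    ]
    return GeneSet(name or f"{result.set_name}_positive", members)
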