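"""Ranking metric, running-sum enrichment score, permutation null, NES/p."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import utrpresence as up
from utrpresence.enrichment import (
    GseaConfig,
    enrichment_score,
    normalize_and_p,
    permutation_null,
    positive_correlation_genes,
    rank_genes,
    run_gsea,
)
from utrpresence.expression import ARM_ANTAGOMIR, ARM_CONTROL


def _matrix(values: np.ndarray, genes=None, arms=None, timepoint=72):
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i:02d}" for i in range(n_genes)]
    arms = arms or [ARM_ANTAGOMIR] * (n_samples // 2) + [ARM_CONTROL] * (
        n_samples - n_samples // 2
    )
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {"arm": arms, "timepoint": timepoint, "replicate": range(n_samples)},
        index=samples,
    )
    return up.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


def brute_force_walk_es(hits: np.ndarray) -> float:
    """Exhaustive evaluation of the unweighted running sum (KS-type walk)."""
    n, k = hits.size, hits.sum()
    total, best = 0.0, 0.0
    for h in hits:
        total += 1.0 / k if h else -1.0 / (n - k)
        if abs(total) > abs(best):
            best = total
    return best


class TestRankGenes:
    def test_identical_means_all_zero_with_tie_order(self):
        values = np.tile([[1.0, 1.0, 1.0, 1.0]], (4, 1))
        m = _matrix(values, genes=["d", "b", "a", "c"])
        ranked = rank_genes(m)
        assert np.all(ranked.scores == 0)
        assert ranked.genes.tolist() == ["a", "b", "c", "d"]

    def test_signal_to_noise_formula(self):
        # class means 4 and 2, both SDs 0.5; raw formula (no sigma floor)
        values = np.array([[3.5, 4.0, 4.5, 1.5, 2.0, 2.5]])
        m = _matrix(values, genes=["g"], arms=[ARM_ANTAGOMIR] * 3 + [ARM_CONTROL] * 3)
        ranked = rank_genes(m, sigma_floor_fraction=0.0)
        assert ranked.scores[0] == pytest.approx((4 - 2) / (0.5 + 0.5))

    def test_matches_per_gene_recomputation(self):
        rng = np.random.default_rng(11)
        values = rng.normal(5, 1, size=(20, 8))
        m = _matrix(values)
        ranked = rank_genes(m)
        floor = 0.2
        for gene, score in zip(ranked.genes, ranked.scores):
            row = values[int(gene[1:])]
            a, b = row[:4], row[4:]
            sa = max(a.std(ddof=1), floor * abs(a.mean()))
            sb = max(b.std(ddof=1), floor * abs(b.mean()))
            expected = (a.mean() - b.mean()) / (sa + sb)
            assert score == pytest.approx(expected)

    def test_single_class_raises(self):
        m = _matrix(np.ones((3, 4)), arms=[ARM_ANTAGOMIR] * 4)
        with pytest.raises(up.InputError):
            rank_genes(m)


class TestEnrichmentScore:
    def test_single_member_at_top_weight0(self):
        ranked = up.RankedList.from_unsorted(
            [f"g{i}" for i in range(10)], np.arange(10, 0, -1, dtype=float)
        )
        res = enrichment_score(ranked, up.GeneSet("s", ["g0"]), weight=0)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g0"]

    def test_four_step_walk_matches_brute_force(self):
        ranked = up.RankedList.from_unsorted(
            ["g0", "g1", "g2", "g3"], [3.0, 2.0, -2.0, -3.0]
        )
        res = enrichment_score(ranked, up.GeneSet("s", ["g1", "g2"]), weight=0)
        hits = np.array([False, True, True, False])
        assert res.es == pytest.approx(brute_force_walk_es(hits))

    def test_bottom_set_has_negative_es(self):
        ranked = up.RankedList.from_unsorted(
            [f"g{i}" for i in range(8)], np.arange(8, 0, -1, dtype=float)
        )
        res = enrichment_score(ranked, up.GeneSet("s", ["g6", "g7"]), weight=0)
        assert res.es < 0
        assert set(res.leading_edge) == {"g6", "g7"}

    def test_running_sum_ends_at_zero_with_weight0(self):
        rng = np.random.default_rng(3)
        ranked = up.RankedList.from_unsorted(
            [f"g{i}" for i in range(30)], rng.normal(size=30)
        )
        res = enrichment_score(ranked, up.GeneSet("s", ["g2", "g9", "g20"]), weight=0)
        assert res.running_scores[-1] == pytest.approx(0.0, abs=1e-12)

    def test_es_ignores_nonmember_identity(self):
        """Relabeling non-members while keeping scores leaves ES unchanged."""
        scores = np.linspace(3, -3, 12)
        genes_a = [f"g{i}" for i in range(12)]
        genes_b = list(genes_a)
        genes_b[0], genes_b[11] = "x0", "x11"  # non-members renamed
        s = up.GeneSet("s", ["g3", "g7"])
        ra = up.RankedList(np.array(genes_a), scores)
        rb = up.RankedList(np.array(genes_b), scores)
        assert enrichment_score(ra, s).es == enrichment_score(rb, s).es

    def test_disjoint_or_covering_sets_raise(self):
        ranked = up.RankedList.from_unsorted(["a", "b", "c"], [3.0, 2.0, 1.0])
        with pytest.raises(up.InputError):
            enrichment_score(ranked, up.GeneSet("s", ["z"]))
        with pytest.raises(up.InputError):
            enrichment_score(ranked, up.GeneSet("s", ["a", "b", "c"]))


class TestNullAndNormalization:
    def test_deterministic_under_seed(self):
        m = _matrix(np.random.default_rng(5).normal(size=(30, 8)))
        s = up.GeneSet("s", [f"g{i:02d}" for i in range(5)])
        a = permutation_null(m, None, s, n_perm=1, seed=7)
        b = permutation_null(m, None, s, n_perm=1, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_random_set_size_raises(self):
        m = _matrix(np.random.default_rng(5).normal(size=(10, 4)))
        s = up.GeneSet("s", [f"g{i:02d}" for i in range(9)])  # |s| = N - 1
        with pytest.raises(up.InputError):
            permutation_null(m, None, s, n_perm=5, seed=0)

    def test_phenotype_mode_needs_two_per_class(self):
        m = _matrix(
            np.random.default_rng(5).normal(size=(10, 3)),
            arms=[ARM_ANTAGOMIR, ARM_CONTROL, ARM_CONTROL],
        )
        s = up.GeneSet("s", ["g00", "g01"])
        with pytest.raises(up.InputError):
            permutation_null(m, None, s, n_perm=5, mode="phenotype", seed=0)

    def test_nominal_p_uniform_under_exchangeable_null(self):
        """Nominal GSEA p of an arbitrary fixed set is uniform on null data."""
        rng = np.random.default_rng(21)
        s = up.GeneSet("s", [f"g{i:02d}" for i in range(12)])
        cfg = GseaConfig(n_perm=99)
        pvals = []
        for rep in range(200):
            m = _matrix(rng.normal(size=(60, 6)))
            res = run_gsea(m, None, [s], cfg, seed=rep)[0]
            pvals.append(res.nominal_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_hand_computed_nes_and_p(self):
        nes, p = normalize_and_p(0.8, [0.2, 0.4, -0.3])
        assert nes == pytest.approx(0.8 / 0.3)
        assert p == pytest.approx(1 / 3)

    def test_null_equal_to_observed(self):
        nes, p = normalize_and_p(0.5, [0.5, 0.5, 0.5])
        assert nes == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_sign_flip_symmetry(self):
        nes, p = normalize_and_p(0.8, [0.2, 0.4, -0.3])
        nes2, p2 = normalize_and_p(-0.8, [-0.2, -0.4, 0.3])
        assert nes2 == pytest.approx(-nes) and p2 == pytest.approx(p)

    def test_no_same_sign_null_raises(self):
        with pytest.raises(up.InputError):
            normalize_and_p(0.8, [-0.2, -0.4])

    def test_p_strictly_positive(self):
        _, p = normalize_and_p(99.0, np.linspace(0.1, 0.5, 50))
        assert 0 < p <= 1


class TestRunGsea:
    def test_empty_set_list(self):
        m = _matrix(np.ones((4, 4)))
        assert run_gsea(m, None, [], GseaConfig(), seed=0) == []

    def test_planted_enrichment_detected(self):
        """PT_50-like set with a planted 1-log2 shift is called enriched."""
        rng = np.random.default_rng(33)
        hits = 0
        s = up.GeneSet("targets", [f"g{i:02d}" for i in range(20)])
        cfg = GseaConfig(n_perm=99)
        for rep in range(40):
            values = rng.normal(7, 0.25, size=(100, 6))
            values[:20, :3] += 1.0  # antagomir arm de-repression
            m = _matrix(values)
            res = run_gsea(m, None, [s], cfg, seed=rep)[0]
            if res.nes > 0 and res.nominal_p <= 0.05:
                hits += 1
        assert hits >= 36  # >= 90%


class TestPositiveCorrelation:
    def test_strictly_positive_rule(self):
        ranked = up.RankedList.from_unsorted(
            ["a", "b", "c", "d"], [1.2, 0.0, -0.5, 2.0]
        )
        s = up.GeneSet("s", ["a", "b", "c"])
        res = enrichment_score(ranked, s, weight=0)
        pos = positive_correlation_genes(res, ranked)
        assert pos.members == frozenset({"a"})

    def test_all_negative_scores_empty(self):
        ranked = up.RankedList.from_unsorted(["a", "b", "c"], [-1.0, -2.0, -3.0])
        s = up.GeneSet("s", ["a", "b"])
        res = enrichment_score(ranked, s, weight=0)
        assert len(positive_correlation_genes(res, ranked)) == 0

    def test_recovers_planted_upregulated_members(self):
        rng = np.random.default_rng(8)
        values = rng.normal(7, 0.05, size=(50, 6))
        planted = [f"g{i:02d}" for i in range(10)]
        values[:10, :3] += 2.0  # de-repressed members
        values[30:32, :3] -= 2.0  # repressed members
        m = _matrix(values)
        ranked = rank_genes(m)
        s = up.GeneSet("s", planted + ["g30", "g31"])
        res = enrichment_score(ranked, s)
        pos = positive_correlation_genes(res, ranked)
        assert pos.members == frozenset(planted)
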