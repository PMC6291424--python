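"""Site-presence ratio, bin classification, PT_50 and the seed scanner."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import utrpresence as up
from utrpresence.site_presence import (
    classify_bins,
    classify_ratio,
    median_exon_depth,
    scan_seed_sites,
    site_presence,
)
from utrpresence.types import BIN_HIGH, BIN_LOW, BIN_MID, BIN_NOT_DETECTED

iv = up.GenomicInterval


class TestMedianExonDepth:
    def test_uniform_depth_returns_that_depth(self, toy_transcript, toy_track):
        assert median_exon_depth(toy_transcript, toy_track) == 100.0

    def test_median_by_enumeration(self):
        t = up.TranscriptModel("G", "G.t", [iv("c", 0, 5)], iv("c", 5, 10))
        track = up.CoverageTrack({"c": np.array([0, 0, 0, 10, 10], dtype=float)})
        assert median_exon_depth(t, track) == 0.0

    def test_empty_coverage_is_zero(self, toy_transcript):
        assert median_exon_depth(toy_transcript, up.CoverageTrack()) == 0.0

    def test_matches_brute_force_on_poisson_depths(self):
        rng = np.random.default_rng(42)
        depths = rng.poisson(50, size=300).astype(float)
        exons = [iv("c", 0, 100), iv("c", 150, 250), iv("c", 300, 400)]
        arr = np.zeros(400)
        arr[0:100], arr[150:250], arr[300:400] = depths[:100], depths[100:200], depths[200:]
        t = up.TranscriptModel("G", "G.t", exons, iv("c", 400, 500))
        got = median_exon_depth(t, up.CoverageTrack({"c": arr}))
        assert got == np.median(depths)
        assert 45 <= got <= 55


class TestSitePresence:
    def test_identity_ratio_is_high_bin(self, toy_transcript, toy_track):
        p = site_presence(toy_transcript, toy_track)
        assert p.max_ratio == pytest.approx(1.0)
        assert p.bin == BIN_HIGH and p.expressed

    def test_max_over_sites(self):
        t = up.TranscriptModel(
            "G", "G.t", [iv("c", 0, 10)], iv("c", 10, 50),
            sites=[iv("c", 12, 20), iv("c", 30, 38)],
        )
        arr = np.full(50, 100.0)
        arr[12:20] = 30.0
        arr[30:38] = 60.0
        p = site_presence(t, up.CoverageTrack({"c": arr}))
        assert p.site_ratios == pytest.approx([0.3, 0.6])
        assert p.max_ratio == pytest.approx(0.6)
        assert p.bin == BIN_MID
        assert p.best_site == iv("c", 30, 38)

    def test_zero_exon_depth_is_not_detected(self, toy_transcript):
        p = site_presence(toy_transcript, up.CoverageTrack())
        assert not p.expressed
        assert p.max_ratio is None
        assert p.bin == BIN_NOT_DETECTED

    def test_recovers_planted_retention(self):
        spec = up.SyntheticSpec(n_genes=1, retention=0.7, seed=5)
        sim = up.simulate_transcripts(spec)
        cov = up.simulate_coverage(sim, spec)
        p = site_presence(sim.models[0], cov)
        assert 0.65 <= p.max_ratio <= 0.75

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_ratios_invariant_under_coverage_scaling(self, c):
        spec = up.SyntheticSpec(n_genes=3, retention=0.6, seed=9)
        sim = up.simulate_transcripts(spec)
        cov = up.simulate_coverage(sim, spec)
        for m in sim.models:
            a = site_presence(m, cov)
            b = site_presence(m, cov.scaled(c))
            assert b.site_ratios == pytest.approx(a.site_ratios)


class TestBins:
    def test_cutpoint_application(self):
        assert classify_ratio(0.95) == BIN_HIGH
        assert classify_ratio(0.9) == BIN_MID  # "ratio > 0.9" is exclusive
        assert classify_ratio(0.5) == BIN_MID
        assert classify_ratio(0.49) == BIN_LOW

    def test_counts_by_example(self):
        presences = [
            up.SitePresence("a", 10, [0.95], 0.95, True, BIN_HIGH),
            up.SitePresence("b", 10, [0.7], 0.7, True, BIN_MID),
            up.SitePresence("c", 10, [0.2], 0.2, True, BIN_LOW),
        ]
        assert classify_bins(presences) == {
            "high": 1, "mid": 1, "low": 1, "not_detected": 0
        }

    def test_empty_input(self):
        assert sum(classify_bins([]).values()) == 0

    @given(
        ratios=st.lists(
            st.floats(min_value=0, max_value=2, allow_nan=False), max_size=50
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_counts_sum_to_input_size(self, ratios):
        presences = [
            up.SitePresence(f"g{i}", 10, [r], r, True, classify_ratio(r))
            for i, r in enumerate(ratios)
        ]
        counts = classify_bins(presences)
        assert sum(counts.values()) == len(ratios)


class TestPt50:
    def test_threshold_zero_keeps_all_expressed(self, reference_fixture):
        full = up.build_pt50(reference_fixture["presences"], threshold=0.0)
        assert len(full) == sum(p.expressed for p in reference_fixture["presences"])

    def test_all_below_threshold_is_empty(self):
        presences = [up.SitePresence("a", 10, [0.2], 0.2, True, BIN_LOW)]
        assert len(up.build_pt50(presences, threshold=0.5)) == 0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, reference_fixture, thresholds):
        t1, t2 = sorted(thresholds)
        n1 = len(up.build_pt50(reference_fixture["presences"], threshold=t1))
        n2 = len(up.build_pt50(reference_fixture["presences"], threshold=t2))
        assert n1 >= n2


def _brute_force_scan(utr: str, mirna: str):
    """Independent sliding-window matcher for canonical seed sites."""
    comp = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}
    rc = lambda s: "".join(comp[c] for c in reversed(s.upper()))
    m = mirna.upper().replace("T", "U")
    utr = utr.upper().replace("U", "T")
    seed7 = rc(m[1:8])  # matches positions 2-8 (m8 + core)
    seed6 = rc(m[1:7])
    out = []
    for i in range(len(utr)):
        if utr[i : i + 7] == seed7 and utr[i + 7 : i + 8] == "A":
            out.append((i, i + 8, "8mer"))
        elif utr[i : i + 7] == seed7:
            out.append((i, i + 7, "7mer-m8"))
        elif utr[i : i + 6] == seed6 and utr[i + 6 : i + 7] == "A":
            if not (i >= 1 and utr[i - 1 : i + 6] == seed7):
                out.append((i, i + 7, "7mer-A1"))
    return sorted(out)


class TestSeedScanner:
    def test_constructed_8mer_found(self):
        utr = "GGGG" + "TCTTGCCA" + "GGGG"  # RC of miR-31 pos 2-8 + A
        hits = scan_seed_sites(utr, up.MIR31)
        assert [(h.start, h.end, h.kind) for h in hits] == [(4, 12, "8mer")]

    def test_no_core_match_is_empty(self):
        assert scan_seed_sites("ACACACACAC", up.MIR31) == []

    def test_invalid_character_raises(self):
        with pytest.raises(up.InputError):
            scan_seed_sites("ACGTN", up.MIR31)

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(123)
        utr = "".join(rng.choice(list("ACGT"), size=10_000))
        # salt the sequence with planted sites of each flavour
        utr = utr[:100] + "TCTTGCCA" + utr[100:500] + "TCTTGCCG" + utr[500:900] + "ACTTGCCA" + utr[900:]
        got = [(h.start, h.end, h.kind) for h in scan_seed_sites(utr, up.MIR31)]
        assert got == _brute_force_scan(utr, up.MIR31)
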