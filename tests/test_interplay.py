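import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gatatriad import interplay
from gatatriad.interplay import (
    AMBIGUOUS,
    BOUND,
    NOT_BOUND,
    PROFILE_BY_TRIPLE,
    UNCLASSIFIED,
    anchors_from_peaksets,
    assign_profiles,
    binding_complexity_score,
    assign_nearest_tss,
    classify_status,
    match_summits,
    pairwise_overlap,
    quantify_occupancy,
    timing_classify,
)
from gatatriad.io import CORE_EXPERIMENTS

from conftest import peakset_from_summits


class TestMatchSummits:
    def test_window_boundary_inclusive(self):
        a = peakset_from_summits([1000])
        b = peakset_from_summits([1069], "Y")
        assert len(match_summits(a, b, window=70).pairs) == 1
        b2 = peakset_from_summits([1071], "Y")
        assert len(match_summits(a, b2, window=70).pairs) == 0

    def test_identical_sets_fully_matched(self):
        a = peakset_from_summits([100, 500, 2000])
        pairing = match_summits(a, peakset_from_summits([100, 500, 2000], "Y"))
        assert pairing.pairs == [(0, 0), (1, 1), (2, 2)]
        assert pairing.unmatched_a == [] and pairing.unmatched_b == []

    def test_each_peak_matched_at_most_once(self):
        a = peakset_from_summits([1000, 1040])
        b = peakset_from_summits([1020], "Y")
        pairing = match_summits(a, b, window=70)
        assert len(pairing.pairs) == 1
        # nearest wins: 1020 is 20 from both; tie broken toward earlier peak
        assert pairing.pairs[0] == (0, 0)

    @given(
        st.lists(st.integers(0, 5000), min_size=0, max_size=30, unique=True),
        st.lists(st.integers(0, 5000), min_size=0, max_size=30, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_pair_count_symmetric(self, sa, sb):
        a = peakset_from_summits(sorted(sa)) if sa else peakset_from_summits([])
        b = peakset_from_summits(sorted(sb), "Y") if sb else peakset_from_summits([], "Y")
        if not sa or not sb:
            assert len(match_summits(a, b).pairs) == 0
            return
        assert len(match_summits(a, b).pairs) == len(match_summits(b, a).pairs)

    @given(
        st.lists(st.integers(0, 5000), min_size=1, max_size=30, unique=True),
        st.lists(st.integers(0, 5000), min_size=1, max_size=30, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_pairs_within_window(self, sa, sb):
        a, b = peakset_from_summits(sorted(sa)), peakset_from_summits(sorted(sb), "Y")
        pairing = match_summits(a, b, window=70)
        for i, j in pairing.pairs:
            assert abs(a[i].summit - b[j].summit) <= 70


class TestClassifyStatus:
    def test_bound_within_window(self):
        other = peakset_from_summits([1040])
        assert classify_status(("chr1", 1000), other) == BOUND

    def test_not_bound_beyond_notbound_window(self):
        other = peakset_from_summits([2700], halfwidth=100)  # peak [2600, 2800)
        assert classify_status(("chr1", 1000), other) == NOT_BOUND

    def test_between_windows_is_ambiguous(self):
        other = peakset_from_summits([1500])
        assert classify_status(("chr1", 1000), other) == AMBIGUOUS

    def test_peak_edge_blocks_not_bound(self):
        # summit at 2150 is far, but the peak body reaches into the 1 kb window
        other = peakset_from_summits([2050], halfwidth=100)  # peak [1950, 2150)
        assert classify_status(("chr1", 1000), other) == AMBIGUOUS

    def test_empty_chromosome_is_not_bound(self):
        other = peakset_from_summits([1000], chrom="chr2")
        assert classify_status(("chr1", 1000), other) == NOT_BOUND

    @given(st.integers(0, 3000))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_bound_window(self, summit):
        other = peakset_from_summits([1000])
        anchor = ("chr1", summit)
        small = classify_status(anchor, other, bound_window=40)
        large = classify_status(anchor, other, bound_window=120)
        if small == BOUND:
            assert large == BOUND


class TestProfiles:
    def test_letter_mapping_exhaustive(self):
        # the 7 letters enumerate exactly the non-empty bound triples
        triples = set(itertools.product([True, False], repeat=3)) - {(False,) * 3}
        assert set(PROFILE_BY_TRIPLE) == triples
        assert sorted(PROFILE_BY_TRIPLE.values()) == list("abcdefg")

    @pytest.mark.parametrize(
        "bound_in,letter",
        [
            (("GATA2_MP",), "a"),
            (("GATA1_E",), "b"),
            (("GATA2_MP", "GATA2_E", "GATA1_E"), "c"),
            (("GATA2_MP", "GATA2_E"), "d"),
            (("GATA2_E",), "e"),
            (("GATA2_MP", "GATA1_E"), "f"),
            (("GATA2_E", "GATA1_E"), "g"),
        ],
    )
    def test_each_letter(self, bound_in, letter):
        sets = {
            exp: peakset_from_summits([5000] if exp in bound_in else [], exp)
            for exp in CORE_EXPERIMENTS
        }
        df = assign_profiles([("chr1", 5000)], *[sets[e] for e in CORE_EXPERIMENTS])
        assert df.loc[0, "letter"] == letter

    def test_ambiguous_gives_unclassified(self):
        sets = {
            "GATA2_MP": peakset_from_summits([5500], "GATA2_MP"),  # ambiguous distance
            "GATA2_E": peakset_from_summits([5000], "GATA2_E"),
            "GATA1_E": peakset_from_summits([5010], "GATA1_E"),
        }
        df = assign_profiles([("chr1", 5000)], *[sets[e] for e in CORE_EXPERIMENTS])
        assert df.loc[0, "letter"] == UNCLASSIFIED

    def test_partition_each_anchor_gets_one_label(self):
        rng = np.random.default_rng(1)
        summits = np.sort(rng.choice(np.arange(3000, 300000, 3000), 50, replace=False))
        sets = []
        for exp in CORE_EXPERIMENTS:
            mask = rng.random(50) < 0.6
            sets.append(peakset_from_summits(list(summits[mask]), exp))
        anchors = anchors_from_peaksets(sets)
        df = assign_profiles(anchors, *sets)
        assert len(df) == len(anchors)
        assert df["letter"].isin(list("abcdefg") + [UNCLASSIFIED]).all()


class TestOverlapAndOccupancy:
    def test_self_overlap_is_one(self):
        a = peakset_from_summits([100, 5000], "A")
        b = peakset_from_summits([100, 5000], "B")
        table = pairwise_overlap({"A": a, "B": b})
        self_frac = table.set_index(["a", "b"]).loc[("A", "A"), "fraction"]
        assert self_frac == 1.0

    def test_disjoint_chromosomes_zero(self):
        a = peakset_from_summits([100], "A", chrom="chr1")
        b = peakset_from_summits([100], "B", chrom="chr2")
        table = pairwise_overlap({"A": a, "B": b}).set_index(["a", "b"])
        assert table.loc[("A", "B"), "fraction"] == 0.0

    def test_empty_set_reported_missing(self):
        a = peakset_from_summits([100], "A")
        b = peakset_from_summits([], "B")
        table = pairwise_overlap({"A": a, "B": b}).set_index(["a", "b"])
        assert np.isnan(table.loc[("B", "A"), "fraction"])

    def test_occupancy_half_open(self):
        assert quantify_occupancy((15, 30), [10, 20, 30]) == 1
        assert quantify_occupancy((0, 100), []) == 0
        assert quantify_occupancy((10, 31), [10, 20, 30]) == 3


class TestTiming:
    def test_first_last_stages(self):
        anchors = [("chr1", 1000), ("chr1", 9000), ("chr1", 20000)]
        stages = {
            "GATA1": {
                "MP": peakset_from_summits([9000]),
                "E1": peakset_from_summits([]),
                "E3": peakset_from_summits([9010]),
                "E5": peakset_from_summits([1000, 9020]),
            }
        }
        df = timing_classify(anchors, stages).set_index("summit")
        assert df.loc[1000, "first_stage"] == "E5" and df.loc[1000, "last_stage"] == "E5"
        assert df.loc[9000, "first_stage"] == "MP" and df.loc[9000, "last_stage"] == "E5"
        assert 20000 not in df.index  # never bound -> absent


class TestNearestTss:
    def test_nearest_and_tie_rule(self):
        tss = pd.DataFrame(
            {
                "gene_id": ["geneB", "geneA", "geneC"],
                "chrom": ["chr1", "chr1", "chr1"],
                "tss_position": [900, 1200, 1100],
                "strand": ["+", "-", "+"],
            }
        )
        peaks = peakset_from_summits([1000])
        out = assign_nearest_tss(peaks, tss)
        # 900 and 1100 are both 100 away -> lexicographically smaller gene id
        assert out.loc[0, "gene_id"] == "geneB"

    def test_unassigned_chromosome(self):
        tss = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr9"], "tss_position": [100], "strand": ["+"]}
        )
        out = assign_nearest_tss(peakset_from_summits([1000]), tss)
        assert out["gene_id"].isna().all()


class TestComplexityScore:
    def test_counts_bound_cells(self):
        status = pd.DataFrame(
            {
                "GATA2_MP": [BOUND, BOUND, NOT_BOUND, BOUND],
                "GATA2_E": [BOUND, BOUND, BOUND, NOT_BOUND],
                "GATA1_E": [BOUND, BOUND, NOT_BOUND, BOUND],
            },
            index=["r0", "r1", "r2", "r3"],
        )
        peak_genes = pd.DataFrame(
            {"gene_id": ["Gfi1b", "Gfi1b", "Gfi1b", "Gfi1b"]},
            index=["r0", "r1", "r2", "r3"],
        )
        # brute force: count 'bound' cells over the gene's regions
        expected = int((status.to_numpy() == BOUND).sum())
        assert binding_complexity_score("Gfi1b", peak_genes, status) == expected
        assert binding_complexity_score("absent", peak_genes, status) == 0

    def test_two_regions_three_experiments(self):
        status = pd.DataFrame(
            {"A": [BOUND, BOUND], "B": [BOUND, BOUND], "C": [BOUND, BOUND]},
            index=["r0", "r1"],
        )
        peak_genes = pd.DataFrame({"gene_id": ["g", "g"]}, index=["r0", "r1"])
        assert binding_complexity_score("g", peak_genes, status) == 6
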