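"""Unit and property tests for the two-locus LD statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lddecay.datatypes import MISSING, HapCounts, HaplotypeSet, make_marker_map
from lddecay.ld import adjacent_pairs, hap_counts, ld_from_counts, ld_pair, pairwise_window

counts_st = st.tuples(*[st.integers(0, 40)] * 4)


def polymorphic(c: HapCounts) -> bool:
    f_A = c.n_AB + c.n_Ab
    f_B = c.n_AB + c.n_aB
    return c.total > 0 and 0 < f_A < c.total and 0 < f_B < c.total


class TestHapCounts:
    def test_identical_columns(self):
        c = hap_counts(np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1]))
        assert (c.n_AB, c.n_Ab, c.n_aB, c.n_ab) == (2, 0, 0, 2)

    def test_all_four_classes(self):
        c = hap_counts(np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1]))
        assert (c.n_AB, c.n_Ab, c.n_aB, c.n_ab) == (1, 1, 1, 1)

    def test_missing_rows_excluded(self):
        a = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=np.int8)
        b = np.array([0, 0, 1, 1, MISSING, 0, 0, 1, 1, MISSING], dtype=np.int8)
        c = hap_counts(a, b)
        assert c.total == 8
        assert (c.n_AB, c.n_Ab, c.n_aB, c.n_ab) == (2, 2, 2, 2)


class TestLdPair:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 0, 0, 10), (0.25, 1.0, 1.0)),  # complete LD, two classes
            ((25, 25, 25, 25), (0.0, 0.0, 0.0)),  # exact independence
            ((4, 1, 1, 4), (0.15, 0.6, 0.36)),  # hand-evaluated frequencies
        ],
    )
    def test_known_values(self, counts, expected):
        d, dp, r2 = ld_pair(HapCounts(*counts))
        assert d == pytest.approx(expected[0], abs=1e-12)
        assert dp == pytest.approx(expected[1], abs=1e-12)
        assert r2 == pytest.approx(expected[2], abs=1e-12)

    def test_monomorphic_locus_is_incomputable(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(HapCounts(5, 5, 0, 0))  # locus 1 fixed for allele A

    def test_zero_rows_is_incomputable(self):
        with pytest.raises(ValueError):
            ld_pair(HapCounts(0, 0, 0, 0))

    @settings(max_examples=300, derandomize=True)
    @given(counts_st)
    def test_bounds_and_ordering(self, counts):
        c = HapCounts(*counts)
        if not polymorphic(c):
            return
        _, dp, r2 = ld_pair(c)
        assert 0.0 <= r2 <= dp * dp + 1e-9
        assert dp <= 1.0

    @settings(max_examples=300, derandomize=True)
    @given(counts_st)
    def test_allele_relabeling_invariance(self, counts):
        c = HapCounts(*counts)
        if not polymorphic(c):
            return
        _, dp, r2 = ld_pair(c)
        # swap labels at locus 1, then at locus 2
        swap1 = HapCounts(c.n_aB, c.n_ab, c.n_AB, c.n_Ab)
        swap2 = HapCounts(c.n_Ab, c.n_AB, c.n_ab, c.n_aB)
        for other in (swap1, swap2):
            _, dp2, r22 = ld_pair(other)
            assert dp2 == pytest.approx(dp, abs=1e-12)
            assert r22 == pytest.approx(r2, abs=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(counts_st)
    def test_locus_swap_symmetry(self, counts):
        c = HapCounts(*counts)
        if not polymorphic(c):
            return
        d, dp, r2 = ld_pair(c)
        d2, dp2, r22 = ld_pair(HapCounts(c.n_AB, c.n_aB, c.n_Ab, c.n_ab))
        assert (d2, dp2, r22) == pytest.approx((d, dp, r2), abs=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(counts_st)
    def test_three_observed_classes_give_full_dprime(self, counts):
        c = HapCounts(*counts)
        if not polymorphic(c):
            return
        n_zero_classes = sum(1 for x in counts if x == 0)
        if n_zero_classes >= 1:
            _, dp, _ = ld_pair(c)
            assert dp == pytest.approx(1.0, abs=1e-9)


def brute_force_pairs(haps: HaplotypeSet, window: int):
    """Independent double-loop enumeration of within-window pairs."""
    out = []
    markers = haps.markers
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            if markers["chromosome"].iloc[i] != markers["chromosome"].iloc[j]:
                continue
            d = abs(int(markers["position"].iloc[j]) - int(markers["position"].iloc[i]))
            if d > window:
                continue
            out.append((i, j, d))
    return out


class TestPairwiseWindow:
    def test_window_cut(self, tiny_haps):
        pairs = pairwise_window(tiny_haps, 100_000)
        chrom1 = pairs[pairs["chromosome"] == "1"]
        # markers at 1000/2000/200000 bp: only the first two pair up
        assert len(chrom1) == 1
        assert chrom1["distance_bp"].iloc[0] == 1000

    def test_no_cross_chromosome_pairs(self, tiny_haps):
        pairs = pairwise_window(tiny_haps, 10_000_000)
        for _, row in pairs.iterrows():
            mi = tiny_haps.markers.set_index("marker_id")
            assert mi.loc[row["marker_i"], "chromosome"] == mi.loc[row["marker_j"], "chromosome"]

    def test_matches_brute_force_enumeration_and_oracle(self):
        rng = np.random.default_rng(11)
        n_mark = 50
        markers = make_marker_map(
            [f"m{k}" for k in range(n_mark)],
            ["1"] * n_mark,
            (np.arange(n_mark) * 5000 + 1).tolist(),
        )
        haps = rng.integers(0, 2, size=(30, n_mark)).astype(np.int8)
        haps[rng.random(haps.shape) < 0.05] = MISSING
        hs = HaplotypeSet(markers=markers, haplotypes=haps)
        pairs = pairwise_window(hs, 100_000)
        expected = brute_force_pairs(hs, 100_000)
        assert len(pairs) == len(expected)
        # spot-check every pair's statistics against the scalar path
        lookup = {
            (r["marker_i"], r["marker_j"]): r for _, r in pairs.iterrows()
        }
        for i, j, d in expected:
            row = lookup[(f"m{i}", f"m{j}")]
            assert row["distance_bp"] == d
            c = hap_counts(haps[:, i], haps[:, j])
            assert row["n_used"] == c.total
            if row["computable"]:
                dd, dp, r2 = ld_pair(c)
                assert row["D"] == pytest.approx(dd, abs=1e-12)
                assert row["dprime_abs"] == pytest.approx(dp, abs=1e-12)
                assert row["r2"] == pytest.approx(r2, abs=1e-12)

    def test_incomputable_pairs_flagged_not_dropped(self):
        markers = make_marker_map(["a", "b"], ["1", "1"], [100, 200])
        haps = np.array([[0, 0], [0, 1], [0, 1], [0, 0]], dtype=np.int8)  # locus a fixed
        pairs = pairwise_window(HaplotypeSet(markers=markers, haplotypes=haps), 1000)
        assert len(pairs) == 1
        assert not bool(pairs["computable"].iloc[0])
        assert np.isnan(pairs["r2"].iloc[0])


class TestAdjacentPairs:
    def test_consecutive_count(self):
        markers = make_marker_map(
            [f"m{k}" for k in range(5)], ["1"] * 5, [1000, 6000, 11000, 16000, 21000]
        )
        haps = np.random.default_rng(0).integers(0, 2, (20, 5)).astype(np.int8)
        adj = adjacent_pairs(HaplotypeSet(markers=markers, haplotypes=haps))
        assert len(adj) == 4
        assert (adj["distance_bp"] == 5000).all()

    def test_single_marker_chromosome_contributes_nothing(self, tiny_haps):
        sub_single = tiny_haps.subset_markers(np.array([0]))
        assert len(adjacent_pairs(sub_single)) == 0

    def test_subset_of_window_engine(self, study_maternal):
        sub = study_maternal.subset_markers(np.arange(40))
        adj = adjacent_pairs(sub)
        win = pairwise_window(sub, 10_000_000)
        merged = adj.merge(
            win, on=["marker_i", "marker_j"], suffixes=("_adj", "_win")
        )
        assert len(merged) == len(adj)
        ok = merged["computable_adj"].astype(bool)
        assert np.allclose(
            merged.loc[ok, "r2_adj"], merged.loc[ok, "r2_win"], atol=1e-12
        )
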