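"""Distance-bin decay tables, exceedance, chromosome summaries, trends."""

import numpy as np
import pandas as pd
import pytest

from lddecay.datatypes import MISSING, DistanceBins, HaplotypeSet, make_marker_map
from lddecay.ld import adjacent_pairs, pairwise_window
from lddecay.summarize import (
    bin_pairs,
    chromosome_summaries,
    exceedance,
    haplotype_maf,
    length_vs_ld,
    maf_sensitivity,
)


def pair_frame(distances_bp, r2, dprime=None, computable=None):
    n = len(distances_bp)
    return pd.DataFrame(
        {
            "chromosome": "1",
            "marker_i": [f"a{k}" for k in range(n)],
            "marker_j": [f"b{k}" for k in range(n)],
            "pos_i": 1,
            "pos_j": 1,
            "distance_bp": distances_bp,
            "n_used": 10,
            "D": 0.0,
            "dprime_abs": dprime if dprime is not None else r2,
            "r2": r2,
            "computable": computable if computable is not None else [True] * n,
        }
    )


class TestBinPairs:
    def test_placement(self):
        out = bin_pairs(pair_frame([500, 1500], [0.5, 0.4]))
        assert out.loc[out["bin_lo_kb"] == 0, "n_pairs"].iloc[0] == 1
        assert out.loc[out["bin_lo_kb"] == 1, "n_pairs"].iloc[0] == 1

    def test_exact_boundary_goes_to_upper_bin(self):
        out = bin_pairs(pair_frame([1000], [0.5]))
        assert out.loc[out["bin_lo_kb"] == 0, "n_pairs"].iloc[0] == 0
        assert out.loc[out["bin_lo_kb"] == 1, "n_pairs"].iloc[0] == 1

    def test_top_edge_closed(self):
        out = bin_pairs(pair_frame([100_000], [0.5]))
        assert out.loc[out["bin_lo_kb"] == 90, "n_pairs"].iloc[0] == 1

    def test_incomputable_pairs_excluded(self):
        out = bin_pairs(pair_frame([500, 600], [0.5, np.nan], computable=[True, False]))
        assert out.loc[out["bin_lo_kb"] == 0, "n_pairs"].iloc[0] == 1

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.integers(1, 100_001, size=200)
        r2 = rng.random(200)
        dp = np.sqrt(r2)
        pairs = pair_frame(d, r2, dp)
        out = bin_pairs(pairs)
        bins = DistanceBins()
        # independent group-by: brute-force masks per bin
        e = np.asarray(bins.edges_kb) * 1000
        for b in range(bins.n_bins):
            if b == bins.n_bins - 1:
                mask = (d >= e[b]) & (d <= e[b + 1])
            else:
                mask = (d >= e[b]) & (d < e[b + 1])
            row = out.iloc[b]
            assert row["n_pairs"] == mask.sum()
            if mask.sum():
                assert row["mean_r2"] == pytest.approx(r2[mask].mean())
                assert row["median_dprime"] == pytest.approx(np.median(dp[mask]))
                assert row["prop_r2_gt_0.3"] == pytest.approx((r2[mask] > 0.3).mean())

    def test_conservation_over_bins(self, study_maternal):
        pairs = pairwise_window(study_maternal, 100_000)
        out = bin_pairs(pairs)
        assert out["n_pairs"].sum() == int(pairs["computable"].sum())


class TestExceedance:
    def test_all_above(self):
        assert exceedance(np.ones(5), 0.3) == 1.0

    def test_boundary_is_strict(self):
        assert exceedance(np.array([0.30, 0.31]), 0.30) == 0.5

    def test_hand_count(self):
        vals = np.array([0.1, 0.2, 0.25, 0.29, 0.31, 0.4, 0.5, 0.9, 0.05, 0.0])
        assert exceedance(vals, 0.3) == pytest.approx(0.4)

    def test_zero_pairs_undefined(self):
        with pytest.raises(ValueError):
            exceedance(np.array([]), 0.3)


class TestChromosomeSummaries:
    def test_even_spacing(self):
        markers = make_marker_map(["a", "b", "c"], ["1"] * 3, [5000, 10000, 15000])
        haps = np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        hs = HaplotypeSet(markers=markers, haplotypes=haps)
        out = chromosome_summaries(hs, adjacent_pairs(hs))
        assert out["mean_dist_kb"].iloc[0] == pytest.approx(5.0)
        assert out["sd_dist_kb"].iloc[0] == pytest.approx(0.0)
        assert out["size_mb"].iloc[0] == pytest.approx(15000 / 1e6)
        assert out["n_snps"].iloc[0] == 3

    def test_matches_brute_force_recomputation(self, study_maternal):
        sub = study_maternal
        adj = adjacent_pairs(sub)
        out = chromosome_summaries(sub, adj)
        for _, row in out.iterrows():
            sel = adj[(adj["chromosome"] == row["chromosome"]) & adj["computable"]]
            assert row["mean_r2"] == pytest.approx(sel["r2"].mean())
            assert row["median_dprime"] == pytest.approx(sel["dprime_abs"].median())
            maf = haplotype_maf(sub)
            idx = (sub.markers["chromosome"] == row["chromosome"]).to_numpy()
            assert row["mean_maf"] == pytest.approx(np.nanmean(maf[idx]))


class TestMafSensitivity:
    def test_threshold_nesting(self, study_maternal):
        maf = haplotype_maf(study_maternal)
        sets = {t: set(np.flatnonzero(maf > t)) for t in (0.05, 0.15)}
        assert sets[0.15] <= sets[0.05]

    def test_filter_no_op_when_all_maf_high(self):
        markers = make_marker_map(["a", "b", "c"], ["1"] * 3, [1000, 3000, 5000])
        haps = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        hs = HaplotypeSet(markers=markers, haplotypes=haps)  # all MAF = 0.5
        out = maf_sensitivity(hs, (0.05, 0.15, 0.3))
        wide = out.pivot_table(index="bin_lo_kb", columns="maf_threshold", values="mean_r2")
        assert np.allclose(
            wide[0.05].to_numpy(), wide[0.3].to_numpy(), equal_nan=True
        )

    def test_infeasible_thresholds_flagged(self):
        markers = make_marker_map(["a", "b"], ["1"] * 2, [1000, 3000])
        haps = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8)  # MAF 0, 0.5
        hs = HaplotypeSet(markers=markers, haplotypes=haps)
        with pytest.raises(ValueError, match="fewer than two"):
            maf_sensitivity(hs, (0.49,))


class TestLengthVsLd:
    def _summ(self, sizes, r2s):
        return pd.DataFrame(
            {
                "chromosome": [str(i + 1) for i in range(len(sizes))],
                "size_mb": sizes,
                "mean_r2": r2s,
            }
        )

    def test_exact_linear_relation(self):
        slope, r = length_vs_ld(self._summ([50, 100, 150], [0.1, 0.2, 0.3]))
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(0.002)

    def test_constant_ld_zero_slope(self):
        slope, _ = length_vs_ld(self._summ([50, 100, 150], [0.2, 0.2, 0.2]))
        assert slope == pytest.approx(0.0)

    def test_hand_computed_ols(self):
        x = np.array([40.0, 60.0, 80.0, 100.0, 120.0])
        y = np.array([0.10, 0.14, 0.13, 0.20, 0.18])
        xc, yc = x - x.mean(), y - y.mean()
        slope_hand = (xc * yc).sum() / (xc * xc).sum()
        r_hand = (xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum())
        slope, r = length_vs_ld(self._summ(x, y))
        assert slope == pytest.approx(slope_hand)
        assert r == pytest.approx(r_hand)

    def test_exclusion_and_minimum_points(self):
        df = self._summ([50, 100, 150, 200], [0.1, 0.2, 0.3, 0.4])
        slope, r = length_vs_ld(df, exclude=["4"])
        assert r == pytest.approx(1.0)
        with pytest.raises(ValueError, match=">= 3"):
            length_vs_ld(df, exclude=["1", "2"])
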