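"""Aggregation of pairwise LD into decay tables and chromosome summaries.

Distance bins are half-open [lo, hi) in kb with the last bin closed, so a
pair at exactly 1 kb belongs to the 1-2 kb bin. Exceedance proportions
use strict inequality (fraction of pairs with statistic > threshold).
Only computable pairs enter the summaries; incomputable pairs are
counted separately by callers.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DistanceBins, HaplotypeSet, MISSING
from .ld import pairwise_window, DEFAULT_WINDOW_BP

#: exceedance thresholds mirrored in the decay table
R2_THRESHOLDS = (0.3, 0.15)
DPRIME_THRESHOLD = 0.8

BIN_COLUMNS = [
    "bin_lo_kb",
    "bin_hi_kb",
    "n_pairs",
    "mean_r2",
    "sd_r2",
    "median_r2",
    "mean_dprime",
    "sd_dprime",
    "median_dprime",
    "prop_r2_gt_0.3",
    "prop_r2_gt_0.15",
    "prop_dprime_gt_0.8",
]


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else np.nan


def exceedance(values: np.ndarray, threshold: float) -> float:
    """Strict-inequality fraction of values above the threshold."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("exceedance undefined for zero pairs")
    return float((v > threshold).mean())


def bin_pairs(pairs: pd.DataFrame, bins: Optional[DistanceBins] = None) -> pd.DataFrame:
    """Per-distance-bin summary of a PairLD frame.

    Returns one row per bin (empty bins kept, statistics NaN): pair count,
    mean/SD/median of r2 and |D'|, and the exceedance proportions.
    """
    bins = bins if bins is not None else DistanceBins()
    ok = pairs.loc[pairs["computable"].astype(bool)]
    idx = bins.assign(ok["distance_bp"].to_numpy() / 1000.0)
    rows = []
    for b in range(bins.n_bins):
        sel = ok.loc[idx == b]
        r2 = sel["r2"].to_numpy(dtype=float)
        dp = sel["dprime_abs"].to_numpy(dtype=float)
        n = len(sel)
        rows.append(
            {
                "bin_lo_kb": bins.edges_kb[b],
                "bin_hi_kb": bins.edges_kb[b + 1],
                "n_pairs": n,
                "mean_r2": r2.mean() if n else np.nan,
                "sd_r2": _sd(r2),
                "median_r2": float(np.median(r2)) if n else np.nan,
                "mean_dprime": dp.mean() if n else np.nan,
                "sd_dprime": _sd(dp),
                "median_dprime": float(np.median(dp)) if n else np.nan,
                "prop_r2_gt_0.3": float((r2 > R2_THRESHOLDS[0]).mean()) if n else np.nan,
                "prop_r2_gt_0.15": float((r2 > R2_THRESHOLDS[1]).mean()) if n else np.nan,
                "prop_dprime_gt_0.8": float((dp > DPRIME_THRESHOLD).mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def chromosome_summaries(
    haps: HaplotypeSet, adjacent: pd.DataFrame, maf: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """One summary row per chromosome.

    Chromosome size is max marker position / 1e6 Mb; spacing statistics
    come from consecutive-marker distances; LD statistics from the
    adjacent-pair frame; MAF from the maternal haplotypes unless a
    precomputed array is passed.
    """
    if maf is None:
        maf = haplotype_maf(haps)
    markers = haps.markers
    rows = []
    for chrom, idx in markers.groupby("chromosome", sort=False).indices.items():
        pos = markers["position"].to_numpy()[idx]
        adj = adjacent.loc[
            (adjacent["chromosome"] == chrom) & adjacent["computable"].astype(bool)
        ]
        dist_kb = np.diff(np.sort(pos)) / 1000.0
        r2 = adj["r2"].to_numpy(dtype=float)
        dp = adj["dprime_abs"].to_numpy(dtype=float)
        m = maf[idx]
        m = m[~np.isnan(m)]
        rows.append(
            {
                "chromosome": chrom,
                "size_mb": pos.max() / 1e6,
                "n_snps": len(idx),
                "mean_dist_kb": dist_kb.mean() if len(dist_kb) else np.nan,
                "sd_dist_kb": _sd(dist_kb),
                "mean_r2": r2.mean() if len(r2) else np.nan,
                "sd_r2": _sd(r2),
                "median_r2": float(np.median(r2)) if len(r2) else np.nan,
                "mean_dprime": dp.mean() if len(dp) else np.nan,
                "sd_dprime": _sd(dp),
                "median_dprime": float(np.median(dp)) if len(dp) else np.nan,
                "mean_maf": m.mean() if len(m) else np.nan,
                "sd_maf": _sd(m),
            }
        )
    return pd.DataFrame(rows)


def haplotype_maf(haps: HaplotypeSet) -> np.ndarray:
    """Minor allele frequency per marker over non-missing haplotype alleles."""
    obs = haps.haplotypes != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(obs, haps.haplotypes, 0).sum(axis=0) / n, np.nan)
    return np.minimum(p, 1.0 - p)


def maf_sensitivity(
    haps: HaplotypeSet,
    thresholds: Sequence[float] = (0.05, 0.10, 0.15),
    bins: Optional[DistanceBins] = None,
    max_distance_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Per-bin mean r2 and |D'| after re-filtering markers at each MAF cutoff.

    Markers are kept when their maternal-haplotype MAF is strictly greater
    than the cutoff, so the retained sets are nested across increasing
    thresholds. Returns a tidy frame (maf_threshold, bin_lo_kb, bin_hi_kb,
    n_pairs, mean_r2, mean_dprime).
    """
    bins = bins if bins is not None else DistanceBins()
    maf = haplotype_maf(haps)
    frames = []
    for thr in thresholds:
        keep = np.where(maf > thr)[0]
        if len(keep) < 2:
            continue
        sub = haps.subset_markers(keep)
        pairs = pairwise_window(sub, max_distance_bp)
        summary = bin_pairs(pairs, bins)
        frames.append(
            pd.DataFrame(
                {
                    "maf_threshold": thr,
                    "bin_lo_kb": summary["bin_lo_kb"],
                    "bin_hi_kb": summary["bin_hi_kb"],
                    "n_pairs": summary["n_pairs"],
                    "mean_r2": summary["mean_r2"],
                    "mean_dprime": summary["mean_dprime"],
                }
            )
        )
    if not frames:
        raise ValueError(
            "every MAF threshold left fewer than two markers; no result"
        )
    return pd.concat(frames, ignore_index=True)


def length_vs_ld(
    chrom_summaries: pd.DataFrame, exclude: Sequence[str] = ()
) -> Tuple[float, float]:
    """OLS slope and Pearson correlation of mean adjacent-pair r2 vs size.

    ``exclude`` drops chromosomes (e.g. outliers) before the fit; at least
    three chromosomes must remain.
    """
    df = chrom_summaries.loc[~chrom_summaries["chromosome"].isin(set(exclude))]
    df = df.dropna(subset=["mean_r2", "size_mb"])
    if len(df) < 3:
        raise ValueError(f"need >= 3 chromosomes for the trend, have {len(df)}")
    res = stats.linregress(df["size_mb"].to_numpy(), df["mean_r2"].to_numpy())
    return float(res.slope), float(res.rvalue)
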