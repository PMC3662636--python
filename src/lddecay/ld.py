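"""Two-locus linkage disequilibrium statistics on phased haplotypes.

For a biallelic marker pair with haplotype frequencies f_AB, f_Ab, f_aB,
f_ab and allele frequencies f_A = f_AB + f_Ab (etc.):

    D    = f_AB - f_A * f_B
    r^2  = D^2 / (f_A * f_a * f_B * f_b)
    D'   = D / min(f_A*f_b, f_a*f_B)   if D > 0
         = D / min(f_A*f_B, f_a*f_b)   if D < 0

and |D'| is reported. D = 0 is defined to give r^2 = |D'| = 0. A pair is
incomputable when either locus is monomorphic among the pairwise-complete
haplotypes (zero denominator); such pairs are flagged, never silently
dropped and never scored as zero LD.
"""

from __future__ import annotations

from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import MISSING, PAIR_COLUMNS, HapCounts, HaplotypeSet

#: statistics within this distance of 0 or 1 are clamped to the boundary
BOUNDARY_TOL = 1e-9

DEFAULT_WINDOW_BP = 100_000


def hap_counts(hap_a: np.ndarray, hap_b: np.ndarray) -> HapCounts:
    """Count two-locus haplotypes over rows where both alleles are observed.

    ``hap_a`` and ``hap_b`` are equal-length allele columns (0/1, -1
    missing) from the same haplotype set.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValueError("haplotype columns differ in length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    return HapCounts(
        n_AB=int(((a == 0) & (b == 0)).sum()),
        n_Ab=int(((a == 0) & (b == 1)).sum()),
        n_aB=int(((a == 1) & (b == 0)).sum()),
        n_ab=int(((a == 1) & (b == 1)).sum()),
    )


def ld_pair(counts: HapCounts) -> Tuple[float, float, float]:
    """(D, |D'|, r^2) from two-locus haplotype counts.

    Raises ``ValueError`` when no haplotypes were counted or a locus is
    monomorphic within the counted rows (callers treating pairs in bulk
    should use :func:`ld_from_counts`, which flags instead of raising).
    """
    n = counts.total
    if n == 0:
        raise ValueError("no pairwise-complete haplotypes: pair incomputable")
    d, dp, r2, ok = ld_from_counts(
        np.array([counts.n_AB]),
        np.array([counts.n_Ab]),
        np.array([counts.n_aB]),
        np.array([counts.n_ab]),
    )
    if not ok[0]:
        raise ValueError("monomorphic locus within counted rows: pair incomputable")
    return float(d[0]), float(dp[0]), float(r2[0])


def ld_from_counts(
    n_AB: np.ndarray, n_Ab: np.ndarray, n_aB: np.ndarray, n_ab: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized LD statistics: (D, |D'|, r^2, computable) per count vector."""
    n_AB = np.asarray(n_AB, dtype=float)
    n_Ab = np.asarray(n_Ab, dtype=float)
    n_aB = np.asarray(n_aB, dtype=float)
    n_ab = np.asarray(n_ab, dtype=float)
    n = n_AB + n_Ab + n_aB + n_ab

    with np.errstate(divide="ignore", invalid="ignore"):
        f_AB = n_AB / n
        f_A = (n_AB + n_Ab) / n
        f_B = (n_AB + n_aB) / n
        f_a = 1.0 - f_A
        f_b = 1.0 - f_B

        d = f_AB - f_A * f_B
        denom = f_A * f_a * f_B * f_b
        computable = (n > 0) & (denom > 0)

        r2 = np.where(computable, d * d / np.where(denom > 0, denom, 1.0), np.nan)
        # normalization differs by the sign of D
        dmax_pos = np.minimum(f_A * f_b, f_a * f_B)
        dmax_neg = np.minimum(f_A * f_B, f_a * f_b)
        dmax = np.where(d > 0, dmax_pos, dmax_neg)
        dprime = np.where(
            computable & (d != 0), np.abs(d) / np.where(dmax > 0, dmax, 1.0), 0.0
        )
        dprime = np.where(computable, dprime, np.nan)

    r2 = _clamp_unit(r2)
    dprime = _clamp_unit(dprime)
    d = np.where(computable, d, np.nan)
    return d, dprime, r2, computable


def _clamp_unit(x: np.ndarray) -> np.ndarray:
    x = np.where((x < 0) & (x > -BOUNDARY_TOL), 0.0, x)
    x = np.where((x > 1) & (x < 1 + BOUNDARY_TOL), 1.0, x)
    return x


def _pair_table_for_chrom(
    markers: pd.DataFrame,
    haps: np.ndarray,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
) -> pd.DataFrame:
    """Assemble a PairLD frame for index pairs (i, j) on one chromosome."""
    obs = haps != MISSING
    alt = haps == 1
    n_pairs = len(pair_i)
    n_AB = np.empty(n_pairs, dtype=np.int64)
    n_Ab = np.empty(n_pairs, dtype=np.int64)
    n_aB = np.empty(n_pairs, dtype=np.int64)
    n_ab = np.empty(n_pairs, dtype=np.int64)
    # group by anchor column i so each column's masks are built once
    order = np.argsort(pair_i, kind="stable")
    pi, pj = pair_i[order], pair_j[order]
    if n_pairs:
        starts = np.flatnonzero(np.r_[True, pi[1:] != pi[:-1]])
        bounds = np.r_[starts, n_pairs]
    else:
        bounds = np.array([0])
    for s, e in zip(bounds[:-1], bounds[1:]):
        i = pi[s]
        js = pj[s:e]
        ok = obs[:, [i]] & obs[:, js]
        ai = alt[:, [i]]
        aj = alt[:, js]
        n_ab_blk = (ok & ai & aj).sum(axis=0)
        n_aB_blk = (ok & ai & ~aj).sum(axis=0)
        n_Ab_blk = (ok & ~ai & aj).sum(axis=0)
        tot = ok.sum(axis=0)
        n_ab[s:e] = n_ab_blk
        n_aB[s:e] = n_aB_blk
        n_Ab[s:e] = n_Ab_blk
        n_AB[s:e] = tot - n_ab_blk - n_aB_blk - n_Ab_blk
    d, dprime, r2, computable = ld_from_counts(n_AB, n_Ab, n_aB, n_ab)

    pos = markers["position"].to_numpy()
    ids = markers["marker_id"].to_numpy()
    return pd.DataFrame(
        {
            "chromosome": markers["chromosome"].iloc[0] if len(markers) else "",
            "marker_i": ids[pi],
            "marker_j": ids[pj],
            "pos_i": pos[pi],
            "pos_j": pos[pj],
            "distance_bp": np.abs(pos[pj] - pos[pi]),
            "n_used": n_AB + n_Ab + n_aB + n_ab,
            "D": d,
            "dprime_abs": dprime,
            "r2": r2,
            "computable": computable,
        },
        columns=PAIR_COLUMNS,
    )


def iter_pairwise_window(
    haps: HaplotypeSet, max_distance_bp: int = DEFAULT_WINDOW_BP
) -> Iterator[pd.DataFrame]:
    """Yield one PairLD frame per chromosome (all pairs within the window).

    Emits every same-chromosome pair (i, j), i < j, with
    |pos_j - pos_i| <= max_distance_bp; incomputable pairs are included
    with ``computable = False``.
    """
    markers = haps.markers
    for chrom, idx in markers.groupby("chromosome", sort=False).indices.items():
        sub = markers.iloc[idx].reset_index(drop=True)
        pos = sub["position"].to_numpy()
        if not (np.diff(pos) >= 0).all():
            raise ValueError(f"markers on chromosome {chrom} are not position-sorted")
        sub_haps = haps.haplotypes[:, idx]
        # upper neighbour bound per anchor via the sorted positions
        hi = np.searchsorted(pos, pos + max_distance_bp, side="right")
        pair_i = np.concatenate(
            [np.full(hi[i] - i - 1, i, dtype=np.intp) for i in range(len(pos))]
        ) if len(pos) else np.empty(0, dtype=np.intp)
        pair_j = np.concatenate(
            [np.arange(i + 1, hi[i], dtype=np.intp) for i in range(len(pos))]
        ) if len(pos) else np.empty(0, dtype=np.intp)
        yield _pair_table_for_chrom(sub, sub_haps, pair_i, pair_j)


def pairwise_window(
    haps: HaplotypeSet, max_distance_bp: int = DEFAULT_WINDOW_BP
) -> pd.DataFrame:
    """All same-chromosome marker pairs within a physical-distance window."""
    frames = list(iter_pairwise_window(haps, max_distance_bp))
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def adjacent_pairs(haps: HaplotypeSet) -> pd.DataFrame:
    """LD between consecutive retained markers of each chromosome.

    Yields n_markers - n_chromosomes rows; a chromosome with fewer than
    two markers contributes none.
    """
    markers = haps.markers
    frames = []
    for chrom, idx in markers.groupby("chromosome", sort=False).indices.items():
        if len(idx) < 2:
            continue
        sub = markers.iloc[idx].reset_index(drop=True)
        pos = sub["position"].to_numpy()
        if not (np.diff(pos) >= 0).all():
            raise ValueError(f"markers on chromosome {chrom} are not position-sorted")
        pair_i = np.arange(len(idx) - 1, dtype=np.intp)
        pair_j = pair_i + 1
        frames.append(_pair_table_for_chrom(sub, haps.haplotypes[:, idx], pair_i, pair_j))
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)
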