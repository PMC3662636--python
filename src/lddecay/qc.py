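"""Marker quality control for dense SNP panels.

Filters follow the usual chip-QC battery for LD studies: markers must be
mapped to an autosome, polymorphic, have minor allele frequency strictly
above the threshold, call rate strictly above 0.90, and heterozygote
excess (H_obs - H_exp) strictly below 0.30. An external exclusion list
stands in for filters that need raw data the pipeline never sees (e.g.
cluster-intensity screens). Exclusions are attributed to the FIRST failing
criterion in a fixed order so reports are deterministic.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypePanel, QcReport, QcThresholds

logger = logging.getLogger(__name__)


def _allele_counts(panel: GenotypePanel) -> Tuple[np.ndarray, np.ndarray]:
    """(non-missing genotype count, alt-allele count) per marker."""
    obs = panel.allele_a != MISSING
    n_called = obs.sum(axis=0)
    n_alt = np.where(obs, panel.allele_a, 0).sum(axis=0) + np.where(
        obs, panel.allele_b, 0
    ).sum(axis=0)
    return n_called, n_alt


def compute_maf(panel: GenotypePanel) -> np.ndarray:
    """Minor allele frequency per marker, min(p, 1-p) over non-missing alleles.

    Markers with no called genotype get NaN (undefined MAF).
    """
    n_called, n_alt = _allele_counts(panel)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, n_alt / (2.0 * n_called), np.nan)
    return np.minimum(p, 1.0 - p)


def call_rate(panel: GenotypePanel) -> np.ndarray:
    """Fraction of individuals with a non-missing genotype, per marker."""
    if panel.n_individuals == 0:
        raise ValueError("panel has no individuals")
    obs = panel.allele_a != MISSING
    return obs.sum(axis=0) / float(panel.n_individuals)


def het_excess(panel: GenotypePanel) -> np.ndarray:
    """H_obs - H_exp per marker.

    H_obs is the heterozygote fraction among called genotypes; H_exp is
    2p(1-p) with p estimated from the same genotypes. NaN where no
    genotype is called.
    """
    obs = panel.allele_a != MISSING
    n_called = obs.sum(axis=0)
    het = obs & (panel.allele_a != panel.allele_b)
    n_called, n_alt = _allele_counts(panel)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = np.where(n_called > 0, het.sum(axis=0) / n_called, np.nan)
        p = np.where(n_called > 0, n_alt / (2.0 * n_called), np.nan)
    return h_obs - 2.0 * p * (1.0 - p)


def apply_filters(
    panel: GenotypePanel, thresholds: Optional[QcThresholds] = None
) -> Tuple[GenotypePanel, QcReport]:
    """Retain markers passing every criterion; account for every exclusion.

    First-failure attribution order: unmapped/non-autosomal -> external
    list -> monomorphic -> low MAF -> low call rate -> heterozygote
    excess. A marker with no called genotype has undefined MAF and is
    attributed to the call-rate criterion. An empty retained set is a
    valid (logged) outcome.
    """
    if panel.n_markers == 0:
        raise ValueError("cannot QC an empty panel")
    thr = thresholds if thresholds is not None else QcThresholds()

    chrom = panel.markers["chromosome"].to_numpy()
    autosomes = set(str(c) for c in thr.autosomes)
    mapped = np.array([c in autosomes for c in chrom]) & (
        panel.markers["position"].to_numpy() >= 1
    )
    external = panel.markers["marker_id"].isin(thr.external_exclusions).to_numpy()
    maf = compute_maf(panel)
    cr = call_rate(panel)
    hx = het_excess(panel)

    has_call = cr > 0
    monomorphic = has_call & (maf == 0)
    # NaN comparisons are False, so all-missing markers fall through to call rate
    with np.errstate(invalid="ignore"):
        low_maf = has_call & ~monomorphic & ~(maf > thr.maf_min)
        low_cr = ~(cr > thr.call_rate_min)
        high_hx = has_call & ~(hx < thr.het_excess_max)

    flags = np.full(panel.n_markers, "", dtype=object)
    for name, mask in (
        ("unmapped", ~mapped),
        ("external", external),
        ("monomorphic", monomorphic),
        ("low_maf", low_maf),
        ("low_call_rate", low_cr),
        ("het_excess", high_hx),
    ):
        flags[(flags == "") & mask] = name
    retained = flags == ""

    ids = panel.markers["marker_id"].to_numpy()
    report = QcReport(
        n_input=panel.n_markers,
        n_unmapped=int((flags == "unmapped").sum()),
        n_external=int((flags == "external").sum()),
        n_monomorphic=int((flags == "monomorphic").sum()),
        n_low_maf=int((flags == "low_maf").sum()),
        n_low_call_rate=int((flags == "low_call_rate").sum()),
        n_het_excess=int((flags == "het_excess").sum()),
        n_retained=int(retained.sum()),
        per_marker_flags={
            str(ids[k]): str(flags[k]) for k in np.flatnonzero(~retained)
        },
    )
    if report.n_retained == 0:
        logger.warning("QC retained zero markers (n_input=%d)", panel.n_markers)
    return panel.subset_markers(retained), report


def maf_spectrum(
    panel_or_maf,
    bin_width: float = 0.05,
    per_chromosome: bool = False,
    chromosomes: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Proportion of markers per MAF bin.

    Bins are half-open [lo, lo + width) with the last bin closed at 0.5,
    so a MAF exactly on an interior edge counts in the upper bin. Accepts
    a GenotypePanel or a precomputed MAF array (then ``chromosomes`` gives
    per-marker labels when ``per_chromosome``).
    Returns a tidy frame: (chromosome,) bin_lo, bin_hi, n, proportion.
    """
    if isinstance(panel_or_maf, GenotypePanel):
        maf = compute_maf(panel_or_maf)
        chromosomes = panel_or_maf.markers["chromosome"].to_numpy()
    else:
        maf = np.asarray(panel_or_maf, dtype=float)
    ok = ~np.isnan(maf)
    maf = maf[ok]

    # snap edges to decimal values so e.g. 3*0.05 compares as 0.15
    edges = np.round(np.arange(0.0, 0.5 + bin_width / 2, bin_width), 12)
    if edges[-1] < 0.5:
        edges = np.append(edges, 0.5)
    idx = np.clip(np.searchsorted(edges, maf, side="right") - 1, 0, len(edges) - 2)

    def _tab(sel: np.ndarray) -> pd.DataFrame:
        counts = np.bincount(idx[sel], minlength=len(edges) - 1)
        total = counts.sum()
        return pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "n": counts,
                "proportion": counts / total if total else np.nan,
            }
        )

    if not per_chromosome:
        return _tab(np.ones(len(maf), dtype=bool))
    if chromosomes is None:
        raise ValueError("per-chromosome spectrum needs chromosome labels")
    chromosomes = np.asarray(chromosomes)[ok]
    frames = []
    for chrom in pd.unique(chromosomes):
        t = _tab(chromosomes == chrom)
        t.insert(0, "chromosome", chrom)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
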