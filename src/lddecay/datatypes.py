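"""Core data containers for the LD-decay pipeline.

Alleles are coded 0/1 (biallelic SNPs only); -1 marks a missing allele.
Marker maps are pandas DataFrames with columns
``marker_id, chromosome, position, ref, alt`` (``position`` is 1-based bp,
VCF convention). Chromosome labels are strings; only labels in the
configured autosome set are analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

MAP_COLUMNS = ["marker_id", "chromosome", "position", "ref", "alt"]

#: default Bos taurus autosome labels, "1".."29"
DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 30))


def _natural_chrom_key(label: str):
    """Sort numerically when the label is an integer string, else after."""
    try:
        return (0, int(label), label)
    except ValueError:
        return (1, 0, label)


def make_marker_map(
    marker_id: Sequence[str],
    chromosome: Sequence[str],
    position: Sequence[int],
    ref: Optional[Sequence[str]] = None,
    alt: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Build a validated marker map DataFrame.

    Marker ids must be unique and positions >= 1. The map is NOT sorted
    here; use :func:`sort_marker_map` for the canonical ordering.
    """
    n = len(marker_id)
    df = pd.DataFrame(
        {
            "marker_id": np.asarray(marker_id, dtype=object),
            "chromosome": np.asarray([str(c) for c in chromosome], dtype=object),
            "position": np.asarray(position, dtype=np.int64),
            "ref": np.asarray(ref if ref is not None else ["A"] * n, dtype=object),
            "alt": np.asarray(alt if alt is not None else ["G"] * n, dtype=object),
        }
    )
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker_id {dup!r} in marker map")
    if (df["position"] < 1).any():
        bad = df.loc[df["position"] < 1, "marker_id"].iloc[0]
        raise ValueError(f"marker {bad!r} has position < 1")
    return df


def sort_marker_map(markers: pd.DataFrame, chrom_order: Optional[Sequence[str]] = None) -> np.ndarray:
    """Return the permutation that sorts a marker map.

    Total, stable order: chromosome (configured order, else natural), then
    position, then marker_id.
    """
    if chrom_order is not None:
        rank = {str(c): i for i, c in enumerate(chrom_order)}
        chrom_key = [
            (0, rank[c], "") if c in rank else (1,) + _natural_chrom_key(c)[1:]
            for c in markers["chromosome"]
        ]
    else:
        chrom_key = [_natural_chrom_key(c) for c in markers["chromosome"]]
    order = sorted(
        range(len(markers)),
        key=lambda i: (chrom_key[i], int(markers["position"].iloc[i]), markers["marker_id"].iloc[i]),
    )
    return np.asarray(order, dtype=np.intp)


@dataclass
class GenotypePanel:
    """Diploid genotypes with phase flags — the QC substrate.

    ``allele_a[i, m]`` / ``allele_b[i, m]`` are the ordered pair of alleles
    of individual ``i`` at marker ``m`` (0/1, or -1 = missing; both alleles
    of a genotype are missing together). ``phased[i, m]`` records whether
    the pair order is meaningful. ``maternal_index[i]`` (0 or 1) says which
    member of the ordered pair is the dam-transmitted haplotype.
    """

    markers: pd.DataFrame
    individuals: List[str]
    allele_a: np.ndarray
    allele_b: np.ndarray
    phased: np.ndarray
    pedigree: Optional[pd.DataFrame] = None  # columns: individual, sire, dam
    maternal_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n_ind, n_mark = len(self.individuals), len(self.markers)
        for name in ("allele_a", "allele_b", "phased"):
            arr = getattr(self, name)
            if arr.shape != (n_ind, n_mark):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n_ind, n_mark)}"
                )
        bad = ((self.allele_a == MISSING) != (self.allele_b == MISSING)).any()
        if bad:
            raise ValueError("half-missing genotype: alleles must be missing together")
        for arr in (self.allele_a, self.allele_b):
            vals = np.unique(arr)
            if not np.isin(vals, [MISSING, 0, 1]).all():
                raise ValueError("alleles must be in {0, 1} or missing")
        if self.maternal_index is not None:
            mi = np.asarray(self.maternal_index)
            if mi.shape != (n_ind,) or not np.isin(np.unique(mi), [0, 1]).all():
                raise ValueError("maternal_index must be one 0/1 entry per individual")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.allele_a == MISSING

    def subset_markers(self, keep: np.ndarray) -> "GenotypePanel":
        """Panel restricted to a boolean mask or index array over markers."""
        return GenotypePanel(
            markers=self.markers.iloc[keep].reset_index(drop=True)
            if np.asarray(keep).dtype != bool
            else self.markers.loc[keep].reset_index(drop=True),
            individuals=list(self.individuals),
            allele_a=self.allele_a[:, keep],
            allele_b=self.allele_b[:, keep],
            phased=self.phased[:, keep],
            pedigree=self.pedigree,
            maternal_index=self.maternal_index,
        )


@dataclass
class HaplotypeSet:
    """Phased 0/1 allele matrix, one row per maternal haplotype."""

    markers: pd.DataFrame
    haplotypes: np.ndarray  # (n_haplotypes, n_markers) int8, -1 = missing
    source_individuals: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.markers):
            raise ValueError(
                f"haplotype matrix {self.haplotypes.shape} does not match "
                f"{len(self.markers)} markers"
            )
        vals = np.unique(self.haplotypes)
        if not np.isin(vals, [MISSING, 0, 1]).all():
            raise ValueError("haplotype alleles must be in {0, 1} or missing")
        if not self.source_individuals:
            self.source_individuals = [f"h{i}" for i in range(self.haplotypes.shape[0])]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, keep) -> "HaplotypeSet":
        keep = np.asarray(keep)
        markers = (
            self.markers.loc[keep] if keep.dtype == bool else self.markers.iloc[keep]
        ).reset_index(drop=True)
        return HaplotypeSet(
            markers=markers,
            haplotypes=self.haplotypes[:, keep],
            source_individuals=list(self.source_individuals),
        )


@dataclass(frozen=True)
class HapCounts:
    """Two-locus haplotype counts over pairwise-complete haplotypes.

    Convention: allele A = 0 at the first locus, B = 0 at the second;
    lower case = allele 1. r-squared and \\|D'| do not depend on labels.
    """

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    @property
    def total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab


PAIR_COLUMNS = [
    "chromosome",
    "marker_i",
    "marker_j",
    "pos_i",
    "pos_j",
    "distance_bp",
    "n_used",
    "D",
    "dprime_abs",
    "r2",
    "computable",
]


@dataclass(frozen=True)
class QcThresholds:
    """Marker-filter thresholds.

    MAF must be strictly greater than ``maf_min``; call rate strictly
    greater than ``call_rate_min``; heterozygote excess (H_obs - H_exp)
    strictly less than ``het_excess_max``.
    """

    maf_min: float = 0.05
    call_rate_min: float = 0.90
    het_excess_max: float = 0.30
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES
    external_exclusions: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")


#: exclusion criteria in first-failure attribution order
QC_CRITERIA = (
    "unmapped",
    "external",
    "monomorphic",
    "low_maf",
    "low_call_rate",
    "het_excess",
)


@dataclass
class QcReport:
    """Per-criterion exclusion accounting; counts sum to n_input."""

    n_input: int
    n_unmapped: int
    n_external: int
    n_monomorphic: int
    n_low_maf: int
    n_low_call_rate: int
    n_het_excess: int
    n_retained: int
    per_marker_flags: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_unmapped
            + self.n_external
            + self.n_monomorphic
            + self.n_low_maf
            + self.n_low_call_rate
            + self.n_het_excess
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"QC counts sum to {total}, expected n_input={self.n_input}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("unmapped", self.n_unmapped),
            ("external", self.n_external),
            ("monomorphic", self.n_monomorphic),
            ("low_maf", self.n_low_maf),
            ("low_call_rate", self.n_low_call_rate),
            ("het_excess", self.n_het_excess),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["criterion", "n_markers"])


@dataclass(frozen=True)
class DistanceBins:
    """Half-open distance bins in kb, [lo, hi); the last bin is closed."""

    edges_kb: Sequence[float] = (0, 1, 2, 3, 4, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges_kb, dtype=float)
        if len(e) < 2 or not (np.diff(e) > 0).all():
            raise ValueError("bin edges must be strictly increasing, >= 2 values")

    @property
    def n_bins(self) -> int:
        return len(self.edges_kb) - 1

    def assign(self, distance_kb: np.ndarray) -> np.ndarray:
        """Bin index per distance; -1 for distances outside [first, last] edge."""
        e = np.asarray(self.edges_kb, dtype=float)
        d = np.asarray(distance_kb, dtype=float)
        idx = np.searchsorted(e, d, side="right") - 1
        idx[d == e[-1]] = self.n_bins - 1  # closed top of last bin
        idx[(d < e[0]) | (d > e[-1])] = -1
        return idx

    def labels(self) -> List[str]:
        e = self.edges_kb
        return [f"{e[i]:g}-{e[i + 1]:g}" for i in range(self.n_bins)]
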