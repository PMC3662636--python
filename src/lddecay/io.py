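"""Reading and writing genotype panels, haplotype matrices and result tables.

VCF (4.x, phased GT fields) is the canonical input, parsed with cyvcf2.
A plain-text "hapmatrix" dialect (whitespace-delimited 0/1/NA matrix plus
a 3-column marker map) exists so small fixtures need no VCF machinery.
All tabular outputs are TSV with a header row.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    GenotypePanel,
    HaplotypeSet,
    make_marker_map,
    sort_marker_map,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_phased_vcf(
    path: PathLike,
    on_multiallelic: str = "skip",
    maternal_index: Optional[np.ndarray] = None,
) -> GenotypePanel:
    """Load a VCF with GT fields into a GenotypePanel.

    Phase flags come from the GT separator ('|' phased, '/' unphased);
    chromosome and 1-based POS are copied verbatim. Non-SNP and
    multi-allelic records are skipped (``on_multiallelic='skip'``) or
    rejected (``'error'``).
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("skip", "error"):
        raise ValueError("on_multiallelic must be 'skip' or 'error'")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain exceptions on bad files
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    a_cols, b_cols, ph_cols = [], [], []
    for n_rec, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or not v.is_snp:
            if on_multiallelic == "error":
                raise ValueError(
                    f"record {v.CHROM}:{v.POS} (#{n_rec}) is not a biallelic SNP"
                )
            continue
        gts = np.asarray(v.genotypes, dtype=np.int64)  # (n_samples, 3)
        if gts.shape[1] < 3:
            raise ValueError(f"malformed GT at {v.CHROM}:{v.POS} (#{n_rec})")
        a = gts[:, 0].astype(np.int8)
        b = gts[:, 1].astype(np.int8)
        # half-missing calls are treated as fully missing
        miss = (a < 0) | (b < 0)
        a[miss] = MISSING
        b[miss] = MISSING
        a_cols.append(a)
        b_cols.append(b)
        ph_cols.append(gts[:, 2].astype(bool))
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if not ids:
        raise ValueError(f"no biallelic SNPs found in {path}")

    markers = make_marker_map(ids, chroms, poss, refs, alts)
    return GenotypePanel(
        markers=markers,
        individuals=samples,
        allele_a=np.column_stack(a_cols),
        allele_b=np.column_stack(b_cols),
        phased=np.column_stack(ph_cols),
        maternal_index=maternal_index,
    )


def read_hapmatrix(
    matrix_path: PathLike,
    map_path: PathLike,
    chrom_order: Optional[Sequence[str]] = None,
) -> HaplotypeSet:
    """Read a whitespace-delimited 0/1/NA haplotype matrix plus marker map.

    Matrix rows are haplotypes; the map file has columns marker_id,
    chromosome, position (header optional). Markers come back sorted by
    (chromosome, position, marker_id) with matrix columns permuted to
    match.
    """
    mat = pd.read_csv(matrix_path, sep=r"\s+", header=None, dtype=str, na_values=["NA"])
    haps = mat.to_numpy(dtype=object)
    out = np.full(haps.shape, MISSING, dtype=np.int8)
    for val, code in (("0", 0), ("1", 1)):
        out[haps == val] = code

    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str, comment="#")
    if list(mp.iloc[0]) [:2] == ["marker_id", "chromosome"]:
        mp = mp.iloc[1:].reset_index(drop=True)
    if mp.shape[1] < 3:
        raise ValueError(f"map file {map_path} needs 3 columns, has {mp.shape[1]}")
    if out.shape[1] != len(mp):
        raise ValueError(
            f"matrix has {out.shape[1]} columns but map lists {len(mp)} markers"
        )
    markers = make_marker_map(
        mp.iloc[:, 0].tolist(),
        mp.iloc[:, 1].tolist(),
        mp.iloc[:, 2].astype(np.int64).tolist(),
    )
    order = sort_marker_map(markers, chrom_order)
    return HaplotypeSet(
        markers=markers.iloc[order].reset_index(drop=True), haplotypes=out[:, order]
    )


def read_pedigree(path: PathLike) -> pd.DataFrame:
    """3-column TSV: individual, sire, dam."""
    ped = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["individual", "sire", "dam"]
    if list(ped.columns[:3]) != expected:
        ped = pd.read_csv(path, sep="\t", header=None, dtype=str, names=expected)
    return ped[expected]


def read_maternal_index(path: PathLike, individuals: Sequence[str]) -> np.ndarray:
    """TSV (individual, index) -> per-individual 0/1 array in panel order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["individual", "maternal_index"]:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, names=["individual", "maternal_index"]
        )
    lookup = dict(zip(df["individual"], df["maternal_index"].astype(int)))
    try:
        return np.array([lookup[i] for i in individuals], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"maternal index missing for individual {exc}") from exc


def extract_maternal_haplotypes(
    panel: GenotypePanel, maternal_rule: str = "error"
) -> HaplotypeSet:
    """One maternal haplotype row per individual.

    Uses ``panel.maternal_index`` when present. Without it,
    ``maternal_rule='first'`` takes the first allele of each phased pair
    (logged as a warning) and ``'error'`` (default) refuses. Unphased
    heterozygous entries are an error naming the individual and marker;
    unphased homozygotes are accepted, since phase carries no information
    there. Missing genotypes become missing haplotype alleles.
    """
    if panel.maternal_index is not None:
        idx = np.asarray(panel.maternal_index, dtype=np.int8)
    elif maternal_rule == "first":
        logger.warning(
            "no maternal-origin metadata: taking the FIRST allele of each "
            "phased pair as maternal"
        )
        idx = np.zeros(panel.n_individuals, dtype=np.int8)
    else:
        raise ValueError(
            "panel has no maternal_index; pass maternal_rule='first' to use "
            "the first allele of each phased pair"
        )

    het = (
        (panel.allele_a != MISSING)
        & (panel.allele_a != panel.allele_b)
        & ~panel.phased
    )
    if het.any():
        i, m = np.argwhere(het)[0]
        raise ValueError(
            f"unphased heterozygous genotype for individual "
            f"{panel.individuals[i]!r} at marker "
            f"{panel.markers['marker_id'].iloc[m]!r}"
        )

    haps = np.where(idx[:, None] == 0, panel.allele_a, panel.allele_b).astype(np.int8)
    return HaplotypeSet(
        markers=panel.markers.copy(),
        haplotypes=haps,
        source_individuals=list(panel.individuals),
    )


def write_tables(
    tables: Dict[str, pd.DataFrame],
    out_dir: PathLike,
    float_fmt: str = "%.6g",
) -> Dict[str, Path]:
    """Write named DataFrames as TSVs (``<name>.tsv``) under ``out_dir``.

    Floats are printed at a fixed precision so identical runs give
    byte-identical files. Returns name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=float_fmt)
        paths[name] = path
    return paths


def write_hapmatrix(haps: HaplotypeSet, matrix_path: PathLike, map_path: PathLike) -> None:
    """Inverse of :func:`read_hapmatrix`."""
    cells = haps.haplotypes.astype(object)
    cells[haps.haplotypes == MISSING] = "NA"
    with open(matrix_path, "w") as fh:
        for row in cells:
            fh.write(" ".join(str(c) for c in row) + "\n")
    haps.markers[["marker_id", "chromosome", "position"]].to_csv(
        map_path, sep="\t", index=False
    )


def write_phased_vcf(panel: GenotypePanel, path: PathLike) -> None:
    """Write a GenotypePanel as a minimal phased VCF 4.2 text file."""
    order = sort_marker_map(panel.markers)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.markers["chromosome"].iloc[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individuals)
            + "\n"
        )
        for m in order:
            row = panel.markers.iloc[m]
            a = panel.allele_a[:, m]
            b = panel.allele_b[:, m]
            ph = panel.phased[:, m]
            gts = [
                "./."
                if a[i] == MISSING
                else f"{a[i]}{'|' if ph[i] else '/'}{b[i]}"
                for i in range(len(a))
            ]
            fh.write(
                f"{row['chromosome']}\t{row['position']}\t{row['marker_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_pedigree(ped: pd.DataFrame, path: PathLike) -> None:
    ped[["individual", "sire", "dam"]].to_csv(path, sep="\t", index=False)


def write_maternal_index(
    individuals: Sequence[str], maternal_index: Iterable[int], path: PathLike
) -> None:
    pd.DataFrame(
        {"individual": list(individuals), "maternal_index": list(maternal_index)}
    ).to_csv(path, sep="\t", index=False)
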