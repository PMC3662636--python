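"""Shared fixtures: handmade panels with designed QC violations and a
session-scoped simulated half-sib study panel."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lddecay.datatypes import MISSING, GenotypePanel, HaplotypeSet, make_marker_map
from lddecay.experiments import scaled_study_config
from lddecay.io import extract_maternal_haplotypes
from lddecay.simulate import simulate_panel

#: seed for the shared study panel, fixed once for the whole suite
STUDY_SEED = 7


def panel_from_genotype_counts(specs, n_individuals=50):
    """Build a GenotypePanel from per-marker genotype count designs.

    Each spec is (marker_id, chromosome, position, n_hom0, n_het, n_hom1,
    n_missing); counts must sum to n_individuals. Genotypes are laid out
    deterministically (hom0 block, then het, hom1, missing).
    """
    ids, chroms, poss = [], [], []
    a_cols, b_cols = [], []
    for marker_id, chrom, pos, n00, n01, n11, nmiss in specs:
        assert n00 + n01 + n11 + nmiss == n_individuals
        a = np.array([0] * n00 + [0] * n01 + [1] * n11 + [MISSING] * nmiss, dtype=np.int8)
        b = np.array([0] * n00 + [1] * n01 + [1] * n11 + [MISSING] * nmiss, dtype=np.int8)
        ids.append(marker_id)
        chroms.append(chrom)
        poss.append(pos)
        a_cols.append(a)
        b_cols.append(b)
    markers = make_marker_map(ids, chroms, poss)
    n_mark = len(ids)
    return GenotypePanel(
        markers=markers,
        individuals=[f"i{k:03d}" for k in range(n_individuals)],
        allele_a=np.column_stack(a_cols),
        allele_b=np.column_stack(b_cols),
        phased=np.ones((n_individuals, n_mark), dtype=bool),
    )


# designed violations: 9 clean, 2 unmapped, 3 monomorphic, 4 low-MAF,
# 1 low call rate, 1 heterozygote excess  (50 diploids per marker)
QC_FIXTURE_SPECS = (
    [(f"clean{k}", "1", 1000 * (k + 1), 25, 20, 5, 0) for k in range(9)]
    + [("unmapX", "X", 500, 25, 20, 5, 0), ("unmap0", "0", 600, 25, 20, 5, 0)]
    + [(f"mono{k}", "2", 1000 * (k + 1), 50, 0, 0, 0) for k in range(3)]
    + [(f"rare{k}", "3", 1000 * (k + 1), 48, 2, 0, 0) for k in range(4)]
    + [("lowcall", "4", 1000, 22, 17, 4, 7)]  # call rate 0.86
    + [("hetx", "4", 2000, 5, 45, 0, 0)]  # H_obs 0.9, H_exp 0.495
)


@pytest.fixture()
def qc_panel():
    return panel_from_genotype_counts(QC_FIXTURE_SPECS)


@pytest.fixture()
def tiny_haps():
    """4 maternal haplotypes x 5 markers on two chromosomes, one missing cell."""
    markers = make_marker_map(
        ["a", "b", "c", "d", "e"],
        ["1", "1", "1", "2", "2"],
        [1000, 2000, 200000, 1500, 6500],
    )
    haps = np.array(
        [
            [0, 0, 1, 0, 1],
            [0, 1, 0, 1, 1],
            [1, 0, 1, 0, 0],
            [1, 1, MISSING, 1, 0],
        ],
        dtype=np.int8,
    )
    return HaplotypeSet(markers=markers, haplotypes=haps)


@pytest.fixture(scope="session")
def study_panel():
    """Scaled simulated half-sib panel shared across the suite (seeded)."""
    cfg = scaled_study_config(seed=STUDY_SEED)
    panel, truth = simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def study_maternal(study_panel):
    _, panel, _ = study_panel
    return extract_maternal_haplotypes(panel)
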