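"""Pre-registered simulation experiments used for validation and demos.

Two study designs live here so tests, examples and reporting scripts all
run the same conditions:

``scaled_study_config``
    A desk-scale version of the half-sib study the package targets
    (two ~1 Mb chromosomes, ~2 kb marker spacing, 440 offspring from 50
    sires, ancestral N = 500 with a 500-generation burn-in). Large enough
    for stable distance-bin decay curves, small enough to simulate in
    well under a minute.

``sved_recovery``
    Parameter-recovery check of the simulator against Sved's
    drift-recombination equilibrium approximation E[r2] = 1/(1 + 4Nc):
    N = 100 diploids evolve for 4N generations with mutation maintaining
    variation, and mean r2 among common sites is measured at map
    distances where 4Nc is 1, 4 and 10.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .ld import pairwise_window
from .simulate import SimConfig, simulate_population
from .summarize import haplotype_maf

#: map distances (bp) and the 4Nc each implies under the sved config
SVED_DISTANCES_BP = (1000, 4000, 10000)
SVED_N = 100
SVED_RECOMB = 2.5e-6  # Morgans/bp: 4Nc = 1 at 1 kb


def scaled_study_config(seed: int) -> SimConfig:
    """Desk-scale half-sib panel emulating the target study's structure."""
    return SimConfig(
        effective_size=500,
        n_generations=500,
        n_chromosomes=2,
        chrom_length_bp=1_000_000,
        n_snps_per_chrom=500,
        mutation_rate=1e-8,
        recomb_rate=2.5e-8,
        n_sires=50,
        n_offspring=440,
        maf_ascertainment_min=0.05,
        n_founder_sites=3000,
        seed=seed,
    )


def sved_config(seed: int) -> SimConfig:
    """One replicate of the Sved-recovery experiment."""
    return SimConfig(
        effective_size=SVED_N,
        n_generations=4 * SVED_N,  # standard equilibrium burn-in
        n_chromosomes=1,
        chrom_length_bp=12_000,
        n_snps_per_chrom=10,
        mutation_rate=2e-6,
        recomb_rate=SVED_RECOMB,
        n_sires=2,
        n_offspring=2,
        maf_ascertainment_min=0.05,
        n_founder_sites=200,
        seed=seed,
    )


def sved_replicate(seed: int, maf_min: float = 0.05) -> Dict[int, Tuple[int, float]]:
    """Mean r2 near each target distance for one simulated replicate.

    Pairs within +/-15% of each target distance among sites with
    population MAF >= ``maf_min`` contribute; returns
    distance -> (n_pairs, mean r2).
    """
    pop, _ = simulate_population(sved_config(seed))
    maf = haplotype_maf(pop)
    sub = pop.subset_markers(np.flatnonzero(maf >= maf_min))
    pairs = pairwise_window(sub, max(SVED_DISTANCES_BP) * 2)
    pairs = pairs.loc[pairs["computable"].astype(bool)]
    out: Dict[int, Tuple[int, float]] = {}
    for d in SVED_DISTANCES_BP:
        sel = pairs.loc[
            (pairs["distance_bp"] >= d * 0.85) & (pairs["distance_bp"] <= d * 1.15)
        ]
        out[d] = (len(sel), float(sel["r2"].mean()) if len(sel) else np.nan)
    return out


def sved_recovery(seed: int, n_replicates: int = 30) -> pd.DataFrame:
    """Replicate-mean r2 vs the Sved expectation 1/(1 + 4Nc).

    Returns one row per target distance: fourNc, expected_r2, mean_r2,
    sd_r2 (across replicate means), n_replicates.
    """
    reps = [sved_replicate(int(seed) + k) for k in range(n_replicates)]
    rows = []
    for d in SVED_DISTANCES_BP:
        means = np.array([r[d][1] for r in reps], dtype=float)
        means = means[~np.isnan(means)]
        four_nc = 4 * SVED_N * SVED_RECOMB * d
        rows.append(
            {
                "distance_bp": d,
                "fourNc": four_nc,
                "expected_r2": 1.0 / (1.0 + four_nc),
                "mean_r2": means.mean(),
                "sd_r2": means.std(ddof=1),
                "n_replicates": len(means),
            }
        )
    return pd.DataFrame(rows)
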