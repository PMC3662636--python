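"""Forward simulation of phased half-sib SNP panels with known LD structure.

A discrete-generation Wright-Fisher population of ``effective_size``
diploids evolves with uniform recombination (crossovers per gamete
~ Poisson(recomb_rate * chrom_length_bp)) and infinite-sites mutation on
top of founder standing variation. Founders start at linkage equilibrium,
so all LD in the output is generated by drift and inheritance; after a
burn-in of a few N generations the r2-vs-distance profile approaches the
drift-recombination equilibrium described by Sved's approximation
E[r2] ~ 1/(1 + 4Nc).

From the final generation, a half-sib study panel is drawn: a small set
of sires, each with many offspring from unique dams - the typical cattle
breeding structure. The dam-transmitted gamete of every offspring is
recorded, giving exact ground truth for maternal-haplotype extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import MISSING, GenotypePanel, HaplotypeSet, make_marker_map


@dataclass
class SimConfig:
    """Full parameterization of the synthetic population.

    Defaults state the full-scale study conditions this generator
    emulates: 795 offspring from 117 sires genotyped on a dense chip
    (~5 kb mean spacing) across 29 autosomes. Tests and examples run
    scaled-down configs.
    """

    effective_size: int = 1000
    n_generations: int = 1000
    n_chromosomes: int = 29
    chrom_length_bp: int = 100_000_000
    n_snps_per_chrom: int = 20_000
    mutation_rate: float = 1e-8  # per bp per generation
    recomb_rate: float = 1e-8  # Morgans per bp (1 cM/Mb)
    n_sires: int = 117
    n_offspring: int = 795
    maf_ascertainment_min: float = 0.05
    seed: int = 0
    #: founder segregating sites per chromosome (standing variation pool);
    #: None means 3 * n_snps_per_chrom
    n_founder_sites: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "effective_size",
            "n_generations",
            "n_chromosomes",
            "chrom_length_bp",
            "n_snps_per_chrom",
            "n_sires",
            "n_offspring",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mutation_rate < 0 or self.recomb_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_offspring < self.n_sires:
            raise ValueError("n_offspring must be >= n_sires")
        if not 0.0 <= self.maf_ascertainment_min <= 0.5:
            raise ValueError("maf_ascertainment_min must be in [0, 0.5]")

    @property
    def founder_sites(self) -> int:
        return (
            self.n_founder_sites
            if self.n_founder_sites is not None
            else 3 * self.n_snps_per_chrom
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown simulation config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulation.

    ``founder_haplotypes`` is aligned to the population marker table
    (ancestral allele 0 at sites that arose by later mutation);
    ``maternal_gametes`` / ``paternal_gametes`` are aligned to the sampled
    panel's markers, one row per offspring; ``breakpoints`` lists realized
    crossover positions in the sampled gametes.
    """

    founder_haplotypes: Optional[np.ndarray] = None
    true_maf: Optional[np.ndarray] = None
    maternal_gametes: Optional[np.ndarray] = None
    paternal_gametes: Optional[np.ndarray] = None
    breakpoints: Optional[pd.DataFrame] = None


def _founder_frequencies(rng: np.random.Generator, n: int, p_min: float = 0.02) -> np.ndarray:
    """Initial allele frequencies, log-uniform (density ~ 1/p) on [p_min, 1-p_min].

    Skews toward rare alleles like a neutral site-frequency spectrum, so
    the ascertained panel shows the chip-like excess of low-MAF SNPs.
    """
    u = rng.random(n)
    return p_min * ((1.0 - p_min) / p_min) ** u


def _evolve_chromosome(
    cfg: SimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wright-Fisher forward pass for one chromosome.

    Returns (positions, final haplotypes (2N, S), founder haplotypes
    aligned to the same columns) with fixed/lost sites pruned.
    """
    n = cfg.effective_size
    L = cfg.chrom_length_bp
    s0 = cfg.founder_sites
    pos = np.unique(rng.integers(1, L + 1, size=int(s0 * 1.2) + 8))
    if len(pos) > s0:
        pos = np.sort(rng.choice(pos, size=s0, replace=False))
    freqs = _founder_frequencies(rng, len(pos))
    haps = (rng.random((2 * n, len(pos))) < freqs).astype(np.int8)
    founders = haps.copy()

    cross_lambda = cfg.recomb_rate * L
    mut_lambda = 2 * n * cfg.mutation_rate * L

    for gen in range(cfg.n_generations):
        parents = rng.integers(n, size=(n, 2))
        gamete_parent = parents.reshape(-1)  # gamete g comes from this parent
        k = rng.poisson(cross_lambda, size=2 * n)
        phase = rng.integers(2, size=2 * n)
        new = np.empty_like(haps)
        plain = k == 0
        rows = 2 * gamete_parent[plain] + phase[plain]
        new[plain] = haps[rows]
        for g in np.flatnonzero(~plain):
            bps = np.sort(rng.integers(1, L + 1, size=k[g]))
            seg = np.searchsorted(bps, pos)
            choose = (phase[g] + seg) % 2
            p = gamete_parent[g]
            new[g] = np.where(choose == 0, haps[2 * p], haps[2 * p + 1])
        haps = new

        if mut_lambda > 0:
            m = rng.poisson(mut_lambda)
            if m:
                newpos = rng.integers(1, L + 1, size=m)
                newpos = np.setdiff1d(np.unique(newpos), pos)
                if len(newpos):
                    cols = np.zeros((2 * n, len(newpos)), dtype=np.int8)
                    cols[rng.integers(2 * n, size=len(newpos)), np.arange(len(newpos))] = 1
                    pos = np.concatenate([pos, newpos])
                    haps = np.concatenate([haps, cols], axis=1)
                    founders = np.concatenate(
                        [founders, np.zeros((founders.shape[0], len(newpos)), dtype=np.int8)],
                        axis=1,
                    )
                    order = np.argsort(pos, kind="stable")
                    pos, haps, founders = pos[order], haps[:, order], founders[:, order]

        if gen % 10 == 9:
            total = haps.sum(axis=0)
            keep = (total > 0) & (total < 2 * n)
            pos, haps, founders = pos[keep], haps[:, keep], founders[:, keep]

    total = haps.sum(axis=0)
    keep = (total > 0) & (total < 2 * n)
    return pos[keep], haps[:, keep], founders[:, keep]


def simulate_population(config: SimConfig) -> Tuple[HaplotypeSet, SimTruth]:
    """Evolve the base population; return its 2N haplotypes and ground truth.

    Chromosomes are labelled "1".."n_chromosomes" and evolve
    independently; bit-identical output follows from the config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    pos_all: List[np.ndarray] = []
    hap_blocks: List[np.ndarray] = []
    founder_blocks: List[np.ndarray] = []
    chrom_labels: List[str] = []
    for c in range(config.n_chromosomes):
        pos, haps, founders = _evolve_chromosome(config, rng)
        pos_all.append(pos)
        hap_blocks.append(haps)
        founder_blocks.append(founders)
        chrom_labels.extend([str(c + 1)] * len(pos))
    total_sites = sum(len(p) for p in pos_all)
    if total_sites == 0:
        raise ValueError(
            "simulation produced zero segregating sites; increase "
            "effective_size, mutation_rate, n_founder_sites or chromosome length"
        )
    positions = np.concatenate(pos_all)
    markers = make_marker_map(
        [f"snp_{c}_{p}" for c, p in zip(chrom_labels, positions)],
        chrom_labels,
        positions,
    )
    haplotypes = np.concatenate(hap_blocks, axis=1)
    founders = np.concatenate(founder_blocks, axis=1)
    n = config.effective_size
    labels = [f"ind{i}_h{j}" for i in range(n) for j in (0, 1)]
    pop = HaplotypeSet(markers=markers, haplotypes=haplotypes, source_individuals=labels)
    truth = SimTruth(
        founder_haplotypes=founders,
        true_maf=np.minimum(haplotypes.mean(axis=0), 1 - haplotypes.mean(axis=0)),
    )
    return pop, truth


def ascertain_snps(
    pop: HaplotypeSet, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> HaplotypeSet:
    """Chip-style SNP ascertainment: evenly spaced subsample of common sites.

    Per chromosome, sites with population MAF >= ``maf_ascertainment_min``
    are candidates; ``n_snps_per_chrom`` of them are picked greedily, each
    grid point of an even target grid taking its nearest unused candidate.
    """
    del rng  # deterministic; signature kept symmetric with the other samplers
    from .summarize import haplotype_maf

    maf = haplotype_maf(pop)
    markers = pop.markers
    keep_all: List[np.ndarray] = []
    for chrom, idx in markers.groupby("chromosome", sort=False).indices.items():
        qualifying = idx[maf[idx] >= config.maf_ascertainment_min]
        n_target = config.n_snps_per_chrom
        if len(qualifying) < n_target:
            raise ValueError(
                f"chromosome {chrom}: only {len(qualifying)} sites with MAF >= "
                f"{config.maf_ascertainment_min}, need {n_target} "
                f"(short by {n_target - len(qualifying)})"
            )
        pos = markers["position"].to_numpy()[qualifying].astype(float)
        grid = (np.arange(n_target) + 0.5) * (config.chrom_length_bp / n_target)
        used = np.zeros(len(pos), dtype=bool)
        chosen = []
        for g in grid:
            j = int(np.searchsorted(pos, g))
            lo, hi = j - 1, j
            while lo >= 0 and used[lo]:
                lo -= 1
            while hi < len(pos) and used[hi]:
                hi += 1
            if lo < 0:
                best = hi
            elif hi >= len(pos):
                best = lo
            else:
                best = lo if g - pos[lo] <= pos[hi] - g else hi
            used[best] = True
            chosen.append(qualifying[best])
        keep_all.append(np.sort(np.asarray(chosen)))
    keep = np.concatenate(keep_all)
    return pop.subset_markers(keep)


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    pos: np.ndarray,
    length_bp: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, List[int]]:
    """One recombinant gamete from a parent's two haplotypes."""
    k = int(rng.poisson(recomb_rate * length_bp))
    phase = int(rng.integers(2))
    if k == 0:
        return (hap_a if phase == 0 else hap_b).copy(), []
    bps = np.sort(rng.integers(1, length_bp + 1, size=k))
    seg = np.searchsorted(bps, pos)
    choose = (phase + seg) % 2
    return np.where(choose == 0, hap_a, hap_b).astype(np.int8), bps.tolist()


def sample_half_sib_panel(
    pop: HaplotypeSet,
    config: SimConfig,
    truth: Optional[SimTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[GenotypePanel, SimTruth]:
    """Draw a phased half-sib study panel from the final generation.

    ``n_sires`` sires and one unique dam per offspring are drawn without
    replacement; each offspring receives a recombinant paternal and
    maternal gamete, with sires assigned multinomially. The slot of the
    maternal haplotype in the ordered genotype pair is randomized per
    offspring and recorded in ``maternal_index``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    n_ind = pop.n_haplotypes // 2
    if config.n_sires + config.n_offspring > n_ind:
        raise ValueError(
            f"need {config.n_sires} sires + {config.n_offspring} unique dams "
            f"but the population has only {n_ind} individuals"
        )
    draw = rng.permutation(n_ind)
    sires = draw[: config.n_sires]
    dams = draw[config.n_sires : config.n_sires + config.n_offspring]
    sire_of = rng.integers(config.n_sires, size=config.n_offspring)

    markers = pop.markers
    chrom_groups = list(markers.groupby("chromosome", sort=False).indices.items())
    n_mark = len(markers)
    maternal = np.empty((config.n_offspring, n_mark), dtype=np.int8)
    paternal = np.empty((config.n_offspring, n_mark), dtype=np.int8)
    bp_rows = []
    for o in range(config.n_offspring):
        s = sires[sire_of[o]]
        d = dams[o]
        for chrom, idx in chrom_groups:
            pos = markers["position"].to_numpy()[idx]
            pg, pbps = _gamete(
                pop.haplotypes[2 * s, idx],
                pop.haplotypes[2 * s + 1, idx],
                pos,
                config.chrom_length_bp,
                config.recomb_rate,
                rng,
            )
            mg, mbps = _gamete(
                pop.haplotypes[2 * d, idx],
                pop.haplotypes[2 * d + 1, idx],
                pos,
                config.chrom_length_bp,
                config.recomb_rate,
                rng,
            )
            paternal[o, idx] = pg
            maternal[o, idx] = mg
            for role, bps in (("paternal", pbps), ("maternal", mbps)):
                for x in bps:
                    bp_rows.append((f"O{o:04d}", role, chrom, x))

    maternal_index = rng.integers(2, size=config.n_offspring).astype(np.int8)
    allele_a = np.where(maternal_index[:, None] == 0, maternal, paternal)
    allele_b = np.where(maternal_index[:, None] == 0, paternal, maternal)

    offspring_ids = [f"O{o:04d}" for o in range(config.n_offspring)]
    pedigree = pd.DataFrame(
        {
            "individual": offspring_ids,
            "sire": [f"S{sire_of[o]:03d}" for o in range(config.n_offspring)],
            "dam": [f"D{o:04d}" for o in range(config.n_offspring)],
        }
    )
    panel = GenotypePanel(
        markers=markers.copy(),
        individuals=offspring_ids,
        allele_a=allele_a,
        allele_b=allele_b,
        phased=np.ones((config.n_offspring, n_mark), dtype=bool),
        pedigree=pedigree,
        maternal_index=maternal_index,
    )
    out = SimTruth(
        founder_haplotypes=truth.founder_haplotypes if truth else None,
        true_maf=truth.true_maf if truth else None,
        maternal_gametes=maternal,
        paternal_gametes=paternal,
        breakpoints=pd.DataFrame(
            bp_rows, columns=["individual", "parent_role", "chromosome", "position"]
        ),
    )
    return panel, out


def inject_missingness(panel: GenotypePanel, rate: float, seed: int) -> GenotypePanel:
    """Set each genotype missing independently with the given probability."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random((panel.n_individuals, panel.n_markers)) < rate
    a = panel.allele_a.copy()
    b = panel.allele_b.copy()
    a[mask] = MISSING
    b[mask] = MISSING
    return GenotypePanel(
        markers=panel.markers.copy(),
        individuals=list(panel.individuals),
        allele_a=a,
        allele_b=b,
        phased=panel.phased.copy(),
        pedigree=panel.pedigree,
        maternal_index=panel.maternal_index,
    )


def simulate_panel(
    config: SimConfig, missing_rate: float = 0.0
) -> Tuple[GenotypePanel, SimTruth]:
    """Convenience: population -> ascertainment -> half-sib panel (seeded)."""
    pop, truth = simulate_population(config)
    chip = ascertain_snps(pop, config)
    panel, truth = sample_half_sib_panel(chip, config, truth=truth)
    if missing_rate > 0:
        panel = inject_missingness(panel, missing_rate, seed=int(config.seed) + 2)
    return panel, truth


def write_sim_outputs(
    panel: GenotypePanel, truth: SimTruth, out_dir, config: Optional[SimConfig] = None
) -> Dict[str, Path]:
    """Write panel VCF, pedigree, maternal-index and truth TSVs."""
    from . import io as vio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    vcf = out_dir / "panel.vcf"
    vio.write_phased_vcf(panel, vcf)
    paths["vcf"] = vcf
    ped = out_dir / "pedigree.tsv"
    vio.write_pedigree(panel.pedigree, ped)
    paths["pedigree"] = ped
    mi = out_dir / "maternal_index.tsv"
    vio.write_maternal_index(panel.individuals, panel.maternal_index, mi)
    paths["maternal_index"] = mi
    if truth.maternal_gametes is not None:
        mat = out_dir / "truth_maternal_gametes.tsv"
        mapf = out_dir / "truth_marker_map.tsv"
        vio.write_hapmatrix(
            HaplotypeSet(
                markers=panel.markers,
                haplotypes=truth.maternal_gametes,
                source_individuals=list(panel.individuals),
            ),
            mat,
            mapf,
        )
        paths["truth_maternal_gametes"] = mat
        paths["truth_marker_map"] = mapf
    if truth.breakpoints is not None:
        bp = out_dir / "truth_breakpoints.tsv"
        truth.breakpoints.to_csv(bp, sep="\t", index=False)
        paths["truth_breakpoints"] = bp
    if config is not None:
        cfgp = out_dir / "sim_config.yaml"
        config.to_yaml(cfgp)
        paths["config"] = cfgp
    return paths
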