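"""Single-config orchestration: QC -> maternal haplotypes -> windowed LD -> tables.

A run produces six TSVs plus a plain-text log in the output directory:

    qc_report.tsv        per-criterion marker exclusion counts
    pair_ld.tsv          one row per marker pair within the window
    ld_by_chromosome.tsv per-autosome summary (size, spacing, adjacent-pair LD, MAF)
    ld_decay_bins.tsv    distance-bin decay table with exceedance proportions
    maf_spectrum.tsv     per-chromosome MAF histogram
    maf_sensitivity.tsv  per-bin mean r2 / |D'| under nested MAF cutoffs

Re-running on identical inputs yields byte-identical files. Any stage
failure aborts with the stage name and removes partial outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as vio
from .datatypes import DistanceBins, HaplotypeSet, QcThresholds
from .ld import adjacent_pairs, pairwise_window, DEFAULT_WINDOW_BP
from .qc import apply_filters, compute_maf, maf_spectrum
from .summarize import (
    bin_pairs,
    chromosome_summaries,
    haplotype_maf,
    maf_sensitivity,
)

logger = logging.getLogger(__name__)

OUTPUT_TABLES = (
    "qc_report",
    "pair_ld",
    "ld_by_chromosome",
    "ld_decay_bins",
    "maf_spectrum",
    "maf_sensitivity",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs, overridable from the CLI."""

    vcf: Optional[str] = None
    hapmatrix: Optional[str] = None
    hapmap: Optional[str] = None  # marker map for the hapmatrix dialect
    pedigree: Optional[str] = None
    maternal_index: Optional[str] = None
    exclusion_list: Optional[str] = None
    maternal_rule: str = "error"  # 'error' | 'first'
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    het_excess_max: float = 0.30
    autosomes: Sequence[str] = tuple(str(i) for i in range(1, 30))
    window_bp: int = DEFAULT_WINDOW_BP
    bin_edges_kb: Sequence[float] = DistanceBins().edges_kb
    maf_thresholds: Sequence[float] = (0.05, 0.10, 0.15)
    #: per-chromosome LD over 'adjacent' pairs or 'window' (all <= window) pairs
    chrom_stat_pairs: str = "adjacent"
    out_dir: str = "ld_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.maternal_rule not in ("error", "first"):
            raise ValueError("maternal_rule must be 'error' or 'first'")
        if self.chrom_stat_pairs not in ("adjacent", "window"):
            raise ValueError("chrom_stat_pairs must be 'adjacent' or 'window'")
        if (self.vcf is None) == (self.hapmatrix is None):
            raise ValueError("exactly one of vcf or hapmatrix+hapmap must be given")
        if self.hapmatrix is not None and self.hapmap is None:
            raise ValueError("hapmatrix input requires a hapmap marker map file")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown pipeline config field(s): {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> QcThresholds:
        excl = frozenset()
        if self.exclusion_list:
            with open(self.exclusion_list) as fh:
                excl = frozenset(line.strip() for line in fh if line.strip())
        return QcThresholds(
            maf_min=self.maf_min,
            call_rate_min=self.call_rate_min,
            het_excess_max=self.het_excess_max,
            autosomes=tuple(str(a) for a in self.autosomes),
            external_exclusions=excl,
        )


def _load_haplotypes(config: PipelineConfig, log: list) -> tuple:
    """Input + QC stages; returns (HaplotypeSet, qc_report frame)."""
    thr = config.thresholds()
    if config.vcf is not None:
        panel = vio.read_phased_vcf(config.vcf)
        if config.maternal_index:
            panel.maternal_index = vio.read_maternal_index(
                config.maternal_index, panel.individuals
            )
        if config.pedigree:
            panel.pedigree = vio.read_pedigree(config.pedigree)
        log.append(f"input_markers\t{panel.n_markers}")
        log.append(f"input_individuals\t{panel.n_individuals}")
        retained, report = apply_filters(panel, thr)
        qc_frame = report.to_frame()
        for _, row in qc_frame.iterrows():
            log.append(f"qc_{row['criterion']}\t{row['n_markers']}")
        haps = vio.extract_maternal_haplotypes(retained, config.maternal_rule)
        spectrum_maf = compute_maf(retained)
        chroms = retained.markers["chromosome"].to_numpy()
    else:
        haps = vio.read_hapmatrix(config.hapmatrix, config.hapmap)
        autosomes = set(str(a) for a in thr.autosomes)
        keep = haps.markers["chromosome"].astype(str).isin(autosomes).to_numpy()
        n_in = len(keep)
        haps = haps.subset_markers(keep)
        qc_frame = pd.DataFrame(
            {
                "criterion": ["input", "unmapped", "retained"],
                "n_markers": [n_in, int(n_in - keep.sum()), int(keep.sum())],
            }
        )
        log.append("qc\tskipped (haplotype-matrix input); autosome filter only")
        log.append(f"input_markers\t{n_in}")
        log.append(f"qc_retained\t{int(keep.sum())}")
        spectrum_maf = haplotype_maf(haps)
        chroms = haps.markers["chromosome"].to_numpy()
    log.append(f"maternal_haplotypes\t{haps.n_haplotypes}")
    return haps, qc_frame, spectrum_maf, chroms


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Execute the full analysis; return the manifest of written files."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    log: list = [f"lddecay_version\t{__version__}", f"seed\t{config.seed}"]
    for name, value in (
        ("maf_min", config.maf_min),
        ("call_rate_min", config.call_rate_min),
        ("het_excess_max", config.het_excess_max),
        ("window_bp", config.window_bp),
        ("maternal_rule", config.maternal_rule),
        ("chrom_stat_pairs", config.chrom_stat_pairs),
    ):
        log.append(f"{name}\t{value}")

    stage = "input/qc"
    try:
        haps, qc_frame, spectrum_maf, chroms = _load_haplotypes(config, log)

        stage = "pairwise LD"
        pairs = pairwise_window(haps, config.window_bp)
        n_bad = int((~pairs["computable"].astype(bool)).sum())
        log.append(f"pairs_within_window\t{len(pairs)}")
        log.append(f"pairs_incomputable\t{n_bad}")

        stage = "summaries"
        bins = DistanceBins(tuple(config.bin_edges_kb))
        bin_table = bin_pairs(pairs, bins)
        adj = adjacent_pairs(haps)
        chrom_pairs = adj if config.chrom_stat_pairs == "adjacent" else pairs
        chrom_table = chromosome_summaries(haps, chrom_pairs)
        spectrum = maf_spectrum(
            spectrum_maf, per_chromosome=True, chromosomes=chroms
        )
        sensitivity = maf_sensitivity(
            haps, tuple(config.maf_thresholds), bins, config.window_bp
        )

        stage = "write tables"
        written = vio.write_tables(
            {
                "qc_report": qc_frame,
                "pair_ld": pairs,
                "ld_by_chromosome": chrom_table,
                "ld_decay_bins": bin_table,
                "maf_spectrum": spectrum,
                "maf_sensitivity": sensitivity,
            },
            out_dir,
        )
        log_path = out_dir / "run_log.txt"
        log_path.write_text("\n".join(log) + "\n")
        written["run_log"] = log_path
    except Exception as exc:
        for path in written.values():
            try:
                path.unlink()
            except OSError:
                pass
        raise StageError(stage, exc) from exc
    return written


def simulate_command(sim_config_path, out_dir) -> Dict[str, Path]:
    """Generate a synthetic half-sib panel from a YAML config file.

    Writes a phased VCF, pedigree, maternal-index and truth files that
    run_pipeline consumes with no edits.
    """
    from .simulate import SimConfig, simulate_panel, write_sim_outputs

    cfg = SimConfig.from_yaml(sim_config_path)
    panel, truth = simulate_panel(cfg)
    paths = write_sim_outputs(panel, truth, out_dir, config=cfg)
    logger.info("simulated panel written with seed %d", cfg.seed)
    return paths
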