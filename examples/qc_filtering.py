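"""Marker quality control on a simulated genotype panel.

Simulates a small half-sib panel, injects 5% missing genotypes, and
applies the default filters (MAF > 0.05, call rate > 0.90, heterozygote
excess < 0.30, autosomes only). Each excluded marker is attributed to
the first criterion it fails.
"""

from lddecay import QcThresholds, SimConfig, apply_filters, simulate_panel
from lddecay.qc import maf_spectrum

cfg = SimConfig(
    effective_size=200,
    n_generations=200,
    n_chromosomes=2,
    chrom_length_bp=500_000,
    n_snps_per_chrom=150,
    n_sires=10,
    n_offspring=80,
    n_founder_sites=900,
    seed=11,
)
panel, _ = simulate_panel(cfg, missing_rate=0.05)

retained, report = apply_filters(panel, QcThresholds(maf_min=0.05))
print(report.to_frame().to_string(index=False))
print(f"\nretained {retained.n_markers}/{panel.n_markers} markers")

# allele-frequency spectrum of the retained markers, 0.05-wide bins
spec = maf_spectrum(retained)
print("\nMAF spectrum (retained markers):")
print(spec.to_string(index=False))
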