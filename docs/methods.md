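# Methods

## LD statistics

For two biallelic loci, let `f_AB` be the frequency of the haplotype
carrying allele A at the first locus and B at the second, with marginal
allele frequencies `f_A`, `f_a = 1 − f_A`, `f_B`, `f_b = 1 − f_B`,
estimated from the observed haplotype counts. Then

- `D = f_AB − f_A·f_B`
- `r² = D² / (f_A·f_a·f_B·f_b)`
- `D′ = D / min(f_A·f_b, f_a·f_B)` when `D > 0`,
  `D′ = D / min(f_A·f_B, f_a·f_b)` when `D < 0`, and `D′ = 0` when
  `D = 0`. The package reports `|D′|`.

These are haplotype-based estimators: no expectation–maximization phase
inference is performed, because the input is already phased. Counts use
pairwise-complete observations — a haplotype contributes to a pair only
if both alleles are non-missing — so different pairs may rest on
different numbers of haplotypes (`n_used` records it). If the observed
counts are monomorphic at either locus the pair is emitted with
`computable = False` and NaN statistics rather than being dropped or
zero-filled, so row counts are conserved and downstream summaries can
state exactly what they averaged over.

Mathematically `0 ≤ r² ≤ |D′|² ≤ 1`, and `|D′| = 1` exactly when at
most three of the four haplotype classes are observed (no recombinant
class). Both facts are exercised by the test suite, together with
invariance to allele relabeling and locus order.

## Marker quality control

Filters (all inequalities strict) and their defaults:

| criterion | rule | default |
|---|---|---|
| autosomal placement | chromosome label in the configured autosome set | `"1"`…`"29"` |
| external exclusion | marker id not in a user-supplied list | empty |
| polymorphism | observed MAF > 0 | — |
| minor allele frequency | MAF > `maf_min` | 0.05 |
| call rate | fraction of non-missing genotypes > `call_rate_min` | 0.90 |
| heterozygote excess | `H_obs − 2p(1−p)` < `het_excess_max` | 0.30 |

Each excluded marker is attributed to the **first** criterion it fails,
in the order above, so the per-criterion counts plus the retained count
always sum to the input count. Markers with no called genotypes are
attributed to call rate. The heterozygote-excess filter targets
clustering artifacts (paralogous sequence, CNVs) that present as too
many heterozygotes; a deficit is not penalized because inbreeding and
family structure legitimately produce one.

## Maternal haplotype extraction

In a half-sib design a few sires father many offspring, so paternal
gametes are heavily duplicated; LD computed over all gametes would be
biased upward by that pseudo-replication. The analysis therefore uses
one dam-transmitted haplotype per offspring. Which member of the phased
allele pair is maternal comes from a per-individual `maternal_index`
(0/1). When no index is available the caller chooses a fallback rule:
`"error"` (default — refuse to guess) or `"first"` (take the first
phase slot, with a warning). Unphased genotypes are accepted only when
homozygous, where the transmitted allele is unambiguous; an unphased
heterozygote is an error naming the individual and marker.

## Windowed pair enumeration and distance binning

All same-chromosome pairs with separation up to `window_bp` (default
100 000 bp) are enumerated with a two-pointer scan over
position-sorted markers; pairs never span chromosomes. Distance bins
are half-open `[lo, hi)` in kb with the default edges
0, 1, 2, 3, 4, 5, 10, 20, …, 100; the last bin is closed so a pair at
exactly the window edge is counted. A pair at an interior edge
(e.g. exactly 1000 bp) falls in the upper bin. Threshold proportions
(`r² > 0.3`, `r² > 0.15`, `|D′| > 0.8`) use strict inequalities.
Per-chromosome summaries use adjacent-marker pairs so each chromosome's
statistic reflects the panel's realized marker spacing.

The MAF-sensitivity summary re-filters markers at each cutoff using
**maternal-haplotype** allele frequencies (the frequencies actually
entering the LD estimator), with strict `>` so retained sets are nested
across increasing cutoffs.

## Simulator

`simulate_population` runs a discrete-generation Wright–Fisher forward
simulation, one chromosome at a time (chromosomes are independent,
which matches free recombination between them):

- **Founders.** `n_founder_sites` biallelic sites per chromosome at
  uniform-random positions, with allele frequencies drawn from a
  log-uniform (1/p) spectrum truncated to [0.02, 0.98] — the standing
  neutral-variation shape — and alleles assigned independently per
  haplotype (linkage equilibrium at generation 0; LD then builds up by
  drift during burn-in).
- **Transmission.** Each of the `2N` gametes per generation picks a
  random parent and recombines its two haplotypes with
  `Poisson(recomb_rate · chrom_length_bp)` crossovers at uniform
  positions. The common zero-crossover case is a vectorized row copy.
- **Mutation.** Infinite-sites: `Poisson(2N · mutation_rate · L)` new
  sites per generation, each a singleton at a fresh position. Fixed and
  lost sites are pruned every 10 generations and at the end.
- **Ascertainment.** `ascertain_snps` emulates chip design: among sites
  with MAF ≥ `maf_ascertainment_min` (default 0.05), it greedily picks
  the nearest unused site to each point of an evenly spaced grid of
  `n_snps_per_chrom` targets, and raises (reporting the shortfall) if
  too few sites qualify.
- **Half-sib sampling.** `sample_half_sib_panel` draws `n_sires` sires
  and `n_offspring` distinct dams without replacement from the final
  generation, assigns each offspring a uniformly random sire, and
  creates each offspring from fresh recombinant gametes of its parents.
  The dam gamete of every offspring is recorded in `SimTruth`, giving
  an exact oracle for the extraction step. Phase-slot order is
  randomized per individual and disclosed via `maternal_index`.

### Parameter defaults

`SimConfig` defaults describe the full-scale target design: 29
autosomes of 100 Mb, 20 000 chip SNPs per chromosome (~5 kb spacing),
795 offspring of 117 sires, ancestral effective size 1000, mutation and
recombination rates 1e-8 per bp (≈1 cM/Mb), 1000 burn-in generations.
`n_founder_sites` defaults to 3× the chip target so ascertainment has
headroom after drift losses.

Tests and examples use two deliberately smaller configurations defined
in `lddecay.experiments` — a choice made for runtime, not a claim about
the target population:

- `scaled_study_config`: two 1 Mb chromosomes, 500 chip SNPs each
  (~2 kb spacing), 440 offspring of 50 sires, N = 500, 500 generations,
  3000 founder sites per chromosome. Small enough to simulate in ~20 s,
  large enough for stable decay curves.
- `sved_config`: N = 100, one 12 kb chromosome, 400 (= 4N) generations
  — a standard burn-in length chosen before looking at results — with
  mutation rate 2e-6 so mutation–drift equilibrium maintains variation
  over the long burn-in, and recombination 2.5e-6/bp so that
  4Nc = 1, 4, 10 at 1, 4, 10 kb.

### Calibration

The simulator is validated against Sved's drift–recombination
equilibrium approximation `E[r²] ≈ 1/(1 + 4Nc)`. Thirty replicates of
`sved_config` are run; in each, mean r² is taken over site pairs with
MAF ≥ 0.05 whose separation lies within ±15% of each target distance.
The acceptance test requires the replicate mean at every distance to be
within 3 standard deviations (across replicate means) of the
approximation. This is a parameter-recovery check of the generative
model, not a fit to any dataset.

## Numerical choices

- LD statistics are clamped to [0, 1] only within 1e-9 of the
  boundary, so genuine violations would surface rather than be hidden.
- MAF-spectrum bin edges are rounded to 12 decimals before comparison
  so that binary-float artifacts (0.05 × 3 ≠ 0.15) do not move
  boundary frequencies across bins; the top bin is closed at 0.5.
- All random streams come from `numpy.random.default_rng` seeded with
  `[seed, stream]` pairs, so population history, half-sib sampling and
  missingness injection are independently reproducible; derived seeds
  stay below 2³¹.
- Output tables are written with `%.6g` formatting; pipeline reruns on
  identical inputs are byte-identical (tested).

## Limitations

- The simulator is neutral and panmictic: no selection, migration,
  population growth or bottlenecks, so it cannot reproduce LD
  signatures of recent selection or admixture.
- Recombination is homogeneous along the chromosome (no hotspots), and
  mutation is infinite-sites (no recurrent or back mutation).
- LD estimators are plain plug-in frequencies; no small-sample bias
  correction (e.g. the 1/n expectation of r² under independence) is
  applied, so very small haplotype counts inflate r².
- Phase is taken as given. The package does not infer haplotypes from
  genotypes; upstream phasing errors propagate directly into the LD
  estimates.
- Genotyping error is not modeled beyond missingness injection.
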