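"""Compute r-squared and |D'| for marker pairs from phased haplotypes.

Builds a tiny haplotype set by hand, computes LD for one pair from raw
two-locus haplotype counts, then runs the windowed all-pairs scan.
"""

import numpy as np

from lddecay import HapCounts, HaplotypeSet, hap_counts, ld_pair, pairwise_window
from lddecay.datatypes import make_marker_map

# eight haplotypes over three markers on one chromosome
markers = make_marker_map(
    ["m1", "m2", "m3"], ["1", "1", "1"], [10_000, 12_500, 60_000]
)
H = np.array(
    [
        [0, 0, 1],
        [0, 0, 0],
        [1, 1, 0],
        [1, 1, 1],
        [0, 0, 0],
        [1, 1, 1],
        [0, 1, 0],
        [1, 0, 1],
    ],
    dtype=np.int8,
)
haps = HaplotypeSet(markers=markers, haplotypes=H)

# one pair, from explicit haplotype-class counts
counts = hap_counts(H[:, 0], H[:, 1])
D, dprime_abs, r2 = ld_pair(counts)
print(f"m1-m2 counts: AB={counts.n_AB} Ab={counts.n_Ab} "
      f"aB={counts.n_aB} ab={counts.n_ab}")
print(f"m1-m2: D={D:.4f}  |D'|={dprime_abs:.4f}  r2={r2:.4f}")

# a fully determined pair: only coupling classes -> complete LD
D, dprime_abs, r2 = ld_pair(HapCounts(n_AB=10, n_Ab=0, n_aB=0, n_ab=10))
print(f"coupling-only pair: |D'|={dprime_abs:.1f}  r2={r2:.1f}")

# all pairs within a 100 kb window
pairs = pairwise_window(haps, max_distance_bp=100_000)
print(pairs[["marker_i", "marker_j", "distance_bp", "dprime_abs", "r2"]]
      .to_string(index=False))
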