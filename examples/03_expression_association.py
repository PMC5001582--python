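"""Compare gene expression at cohesive versus non-cohesive sites.

Each peak inherits the RPKM of its most highly expressed overlapping
gene; the two groups are compared with the one-sided Wilcoxon rank-sum
test and verified by a label-shuffling permutation test.
"""

import numpy as np

from cohescan import (
    boxplot_summary,
    call_peaks,
    default_config,
    group_expression,
    landscape_config,
    overlap_partition,
    permutation_pvalue,
    rank_sum_one_sided,
    simulate_genes,
    simulate_tracks,
)

config = landscape_config(n_query_peaks=150, n_reference_peaks=80,
                          cohesive_fraction=0.33, seed=8)
tracks, truth = simulate_tracks(config)
rad21 = call_peaks(*tracks["Rad21"], default_config("Rad21"))
mis4 = call_peaks(*tracks["Mis4"], default_config("Mis4"))
split = overlap_partition(rad21, mis4)
genes = simulate_genes(config, truth, query_label="Rad21")

pos, neg = group_expression(split, genes)
rs = rank_sum_one_sided(pos, neg, alternative="greater")
pm = permutation_pvalue(pos, neg, statistic="median_diff", n_perm=10_000,
                        seed=1, alternative="greater")

for name, vals in (("cohesive", pos), ("non-cohesive", neg)):
    s = boxplot_summary(vals)
    print(f"{name:>13}: n={len(vals):>3}  median RPKM={s.median:7.1f}  "
          f"IQR=[{s.q1:.1f}, {s.q3:.1f}]")
print(f"one-sided rank-sum p = {rs.p_value:.3g}  ({rs.method})")
print(f"permutation p (median diff, 10k shuffles) = {pm.p_value:.3g}")
print("A tiny p-value in both tests says cohesive sites sit on markedly "
      "more expressed genes than non-cohesive ones — the planted contrast "
      "(median 700 vs 50 RPKM) recovered through the whole pipeline.")
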