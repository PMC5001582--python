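# cohescan

Peak calling and cohesive-site analysis for cohesin ChIP-chip tiling data
in fission yeast.

## The problem

Cohesin, the ring-shaped SMC complex that holds sister chromatids
together, binds chromosome arms at many sites — but not all bound cohesin
is cohesive. In *S. pombe*, cohesin (Rad21) peaks that co-localize with
the loader complex (Mis4-Ssl3) hold chromatids together, while
loader-free cohesin associates dynamically and does not. Distinguishing
the two populations, and showing that the cohesive one coincides with
highly expressed RNA-polymerase-II genes, takes a chain of genomics
operations: calling peaks on whole-cell-extract-normalized tiling
signal, partitioning peak sets by overlap, assigning gene expression to
peaks, profiling distances to auxiliary factors (Pds5, Sfc6, Swi6), and
testing group differences. `cohescan` implements that chain as a tested,
reusable library for anyone re-analysing two-channel tiling-array ChIP
data or building comparable synthetic benchmarks.

## The method in brief

For probes at positions $x_i$ with IP and WCE intensities, enrichment is
$v_i = \log_2(\mathrm{IP}_i/\mathrm{WCE}_i)$. The caller finds local
maxima with $v \ge \theta$ (per-dataset threshold: 0.3 for Rad21, 0.4 for
Swi6, 0.5 for Mis4/Sfc6, 0.7 otherwise) that rise by at least the
selectivity $sel = 0.2$ above the surrounding signal, extends each apex
outward until $v \le 0$ (where the control overtakes the specific
signal), and keeps intervals with width $\ge 1000$ bp and mean log2
signal above a per-dataset floor (0.2/0.3/0.4 by the same tiers). Cohesin
peaks are then split by $\ge 1$ bp overlap with loader peaks into
cohesive (Mis4+/Rad21+) and non-cohesive (Rad21+) sets; each peak
inherits the RPKM of its most expressed overlapping gene; and the groups
are compared with a one-sided Wilcoxon rank-sum test
(exact for small tie-free samples, tie/continuity-corrected normal
otherwise), verified by a seeded label-shuffling permutation test.
Pooled FISH single/double-dot counts are compared with a Fisher
two-proportion test. Details, parameter tables and design rationale are
in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a cohesin/loader landscape in which a third of 150 cohesin peaks
are co-planted with loader peaks and cohesive-site genes are highly
expressed, then recover that structure end to end
(`examples/03_expression_association.py`):

```python
from cohescan import (landscape_config, simulate_tracks, simulate_genes,
                      call_peaks, default_config, overlap_partition,
                      group_expression, rank_sum_one_sided)

config = landscape_config(n_query_peaks=150, n_reference_peaks=80,
                          cohesive_fraction=0.33, seed=8)
tracks, truth = simulate_tracks(config)
rad21 = call_peaks(*tracks["Rad21"], default_config("Rad21"))
mis4  = call_peaks(*tracks["Mis4"], default_config("Mis4"))
split = overlap_partition(rad21, mis4)
genes = simulate_genes(config, truth, query_label="Rad21")
pos, neg = group_expression(split, genes)
print(rank_sum_one_sided(pos, neg, alternative="greater"))
```

The full script (which also prints boxplot summaries and the permutation
check) outputs:

```
     cohesive: n= 50  median RPKM=  854.4  IQR=[334.6, 1419.7]
 non-cohesive: n=105  median RPKM=   70.1  IQR=[44.6, 126.7]
one-sided rank-sum p = 2.75e-19  (wilcoxon-ranksum-asymptotic)
permutation p (median diff, 10k shuffles) = 0.0001
```

The 50 cohesive peaks sit on genes with a ~12× higher median expression
than the 105 non-cohesive ones, and both tests reject equality — the
planted two-stratum structure (median 700 vs 50 RPKM) recovered through
peak calling, overlap classification and expression assignment.

Each script in `examples/` demonstrates one capability the same way:
peak calling, cohesive classification, expression association, distance
profiles, FISH statistics, and the file-based end-to-end pipeline. A thin
CLI mirrors the stages
(`cohescan simulate | callpeaks | classify | categorize | associate |
distances | test | run`).

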