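# Methods

## Scope and model

`cohescan` analyses cohesin occupancy on fission-yeast chromosome arms from
two-channel tiling-array data. The measurement model is: each probe *i* at
position *x_i* reports an immunoprecipitated intensity `IP_i` and a
whole-cell-extract control intensity `WCE_i`; enrichment is the per-probe
log-ratio `v_i = log2(IP_i / WCE_i)`. Probes with a non-positive value in
either channel have no defined ratio; they are masked and excluded from all
downstream computation (and act as hard stops for peak extension, since
they carry no evidence of enrichment).

All internal coordinates are 0-based half-open. GFF3 input (1-based
inclusive) is converted on read; BED is native. Overlap anywhere in the
package means intersection by at least 1 bp under half-open semantics —
abutting intervals do not overlap, but their margin distance is 0.

## Peak caller

The caller has five parameters:

| parameter         | meaning                                        | default |
|-------------------|------------------------------------------------|---------|
| `min_threshold`   | minimum apex height (log2 units)               | per dataset, see below |
| `sel`             | required rise above the surrounding signal     | 0.2 |
| `min_width_bp`    | minimum peak width (bp)                        | 1000 |
| `min_mean`        | minimum mean log2 signal across the peak       | per dataset |
| `extension_floor` | log2 level at which extension stops            | 0.0 |

Per-dataset tiers (`default_config`): Rad21 → threshold 0.3 / mean 0.2;
Swi6 → 0.4 / 0.3; Mis4 and Sfc6 → 0.5 / 0.3; every other label (Psc3,
Pds5, Ssl3, no-tag controls, novel datasets) → 0.7 / 0.4. Labels are
matched case-insensitively; any parameter can be overridden explicitly.

Apex selection is defined canonically as follows (the selectivity-style
scanning of the classic MATLAB-family peak finders does not pin down
plateau and nesting behaviour, so a single unambiguous definition is fixed
here and enforced by a second, independently coded naive implementation in
`cohescan.reference`):

1. Masked probes split the track into segments; each segment is processed
   alone.
2. A *candidate* is the leftmost index of a value plateau strictly higher
   than the adjacent differing values on both sides. Segment edges never
   qualify. Candidates below `min_threshold` are discarded.
3. Candidates are visited in order of decreasing value, ties leftmost
   first. A candidate is accepted iff the signal dips to at least `sel`
   below its value between it and the nearest already-accepted candidate
   on each side (segment edges serve as bounds where no accepted
   neighbour exists).

Step 3 makes the "higher of two insufficiently separated maxima wins" rule
order-independent, absorbs shoulders into their parent peak, and resolves
equal-height ties to the left.

Each accepted apex is extended probe-by-probe in both directions while the
signal stays strictly above `extension_floor`; the peak interval is
`[position of first kept probe, position of last kept probe + spacing)`,
where spacing is the median inter-probe gap. The half-open tail of one
spacing reflects that a probe measures the fragment population starting at
its coordinate; widths are therefore integer multiples of the spacing on a
regular grid. Overlapping extended intervals (two apexes in one positive
run) are unioned. Surviving intervals are filtered on width and on the
mean of the unmasked probe values inside the interval, and scored with
mean, sum, probe count and apex (leftmost highest probe).

Consequences worth knowing: a maximal positive run of *k* probes spans
`k * spacing` bp, so at 250-bp spacing the 1000-bp width filter admits runs
of four probes; the caller's false calls on pure noise are precisely such
short runs whose mean clears `min_mean`.

## Classification and association

- `overlap_partition` splits a query peak set by ≥1-bp overlap with a
  reference set after padding both sides of both sets by `pad_bp`
  (default 0 for tiling-array sets; 200 is the appropriate value for
  sequencing-derived peaks, matching a typical sonication fragment size).
- Polymerase classes: annotation features typed tRNA or 5S rRNA are
  RNAPIII, everything else RNAPII. Peaks are categorized RNAPII-only,
  RNAPIII-only, both, or none by gene overlap.
- Expression assignment: a peak inherits the maximum RPKM over its
  overlapping genes; genes with unknown RPKM never win, even against
  RPKM 0, and a peak with no expression-bearing overlap is missing and
  excluded from group statistics.
- Margin distance between peaks is 0 for any overlap, otherwise the gap
  between the facing margins. Distance profiles bin `[k*w, (k+1)*w)` with
  `w` = 5000 bp by default and normalize by the full group size, missing
  distances included in the denominator (a flag switches to
  non-missing-only).
- Expression histograms use half-open bins; the default edges run
  0, 150, …, 1500 with an open final bin, chosen to resolve the
  low-expression mass where most non-cohesive genes sit while keeping a
  dedicated tail for highly expressed genes.

## Statistics

- `rank_sum_one_sided`: Wilcoxon rank-sum / Mann-Whitney U via
  `scipy.stats.mannwhitneyu`. For tie-free pooled samples of ≤ 12 values
  the exact null distribution is enumerated; otherwise the normal
  approximation with tie and continuity corrections is used. The path
  taken is recorded in the result. Degenerate (constant pooled) input
  returns p = 1 with a warning.
- `permutation_pvalue`: label-shuffling null for a configurable statistic
  (difference of medians by default; difference of means and rank-sum are
  available), add-one estimator `p = (1 + hits) / (n_perm + 1)` so p is
  never 0, explicit seed, chunked vectorized shuffling.
- `boxplot_summary`: type-7 (linear interpolation) quartiles; whiskers at
  the most extreme values inside `q1 − 1.5·IQR` and `q3 + 1.5·IQR`;
  everything outside is an outlier. Every input value is either inside
  the whiskers or listed — a partition, enforced by tests.
- FISH dot counts: with per-replicate single-dot fractions, a paired
  t-test across replicates; with only pooled counts, a two-sided
  two-proportion test (Fisher exact by default, pooled-z optional). The
  two interfaces are deliberately separate so it is always explicit which
  evidence a p-value rests on.

## Synthetic data generator

`simulate_tracks` emulates the structure the analysis assumes:

- probes on a regular grid (default 250 bp) across one chromosome
  (default 4.5 Mb, the scale of *S. pombe* chromosome-2 arm coverage);
- planted enriched intervals per dataset, rectangular in log2 space
  (height default 1.0, width 2000 bp) with an optional linear shoulder —
  both shapes are exercised in tests because the extension rule is
  sensitive to shoulder decay;
- `WCE = baseline · 2^η`, `IP = WCE · 2^(h(x) + ε)` with η, ε i.i.d.
  Normal(0, `noise_sd`), default 0.15: multiplicative log-normal noise on
  both channels, so the normalized track is exactly `h(x) + ε`;
- `landscape_config` plants a cohesin set and a loader set with a
  configurable co-planted (cohesive) fraction, default 0.33 of 283
  cohesin vs 150 loader peaks — the chromosome-2 scale — and keeps one
  cohesin peak per ~16 kb when the count is scaled down;
- `simulate_genes` centres one gene on every planted cohesin peak and
  fills the background (one gene per ~3 kb, 4% RNAPIII); expression is
  log-normal with median 700 RPKM at cohesive sites and 50 elsewhere
  (σ_log = 1), mirroring the contrast between highly expressed cohesive
  loci and the bulk of the transcriptome;
- `simulate_fish_counts` draws per-replicate binomial single-dot counts.

What the generator does *not* emulate: probe-specific affinity biases and
spatial noise correlation, array-edge effects, copy-number and repeat
artifacts, hyper-ChIPable loci, overlapping genes, and real gene-length /
expression joint structure. Passing the recovery benchmarks therefore
shows the algorithms are correct under the stated statistical model, not
that the per-dataset thresholds are optimal for any particular array.

## Benchmark problem sizes and observed behaviour

The validation harness (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) uses: 500 random ≤ 50-probe tracks for
exact equivalence with the naive reference caller; one 50-peak noiseless
landscape; ten 100-peak landscapes at noise 0.15 (pooled, 1000 truth
peaks); 2000 null simulations at n = 20 per group for rank-sum
calibration; 10⁵ permutations for the permutation/exact comparison; and
100 seeded end-to-end two-stratum runs. These sizes keep the whole
harness around ten seconds on one core while leaving Monte-Carlo error
well below the margins being checked.

At the default noise conditions the caller's recall on planted peaks is
1.0 and its precision fluctuates around 0.95: the residual false calls
are four-to-five-probe noise runs that genuinely satisfy every rule
(width ≥ 1000 bp, mean ≥ 0.2, apex ≥ 0.3 ≈ 2σ). This is an operating
characteristic of the default parameter tiers under i.i.d. probe noise,
not an implementation artifact — the caller is exactly equivalent to the
independent reference implementation. Raising `min_mean` or requiring a
fifth probe would trade those false calls against sensitivity to narrow
true peaks.

## Numerical and design choices

- Duplicate probe positions are input errors, not averaged: tiling
  platforms have unique probe coordinates, and silent averaging would
  mask upstream processing bugs.
- The legacy-annotation coordinate shift (e.g. the 80,031-bp offset on
  chromosome 2 between annotation generations) is a generic piecewise
  `OffsetMap` supplied by configuration. Only the magnitude of such
  shifts is publicly documented, not the breakpoints, so hard-coding one
  would be false precision; identity is the default.
- Peaks written to BED carry `mean_log2`/`sum_log2`/apex/probe-count as
  extra columns with full `repr` precision, so write → read round-trips
  scores exactly.
- `PeakSet` enforces sortedness and per-chromosome disjointness;
  `Peak` enforces `mean == sum / n` to 1e-9 relative tolerance.
- Nearby-peak pooling (`pool_within`, e.g. 10 kb for broad RNAPII
  sequencing peaks) exists but defaults off; it is a preprocessing
  convenience, not part of the tiling-array pipeline.
- All stochastic components take explicit seeds; the pipeline echoes
  every threshold, pad, bin width and seed into its log and summary.

## Known limitations

- The caller assumes a (locally) regular probe grid; on strongly
  irregular grids the interval convention `[first, last + median gap)`
  can disagree with per-gap conventions.
- Probe tracks are single-chromosome by construction; multi-chromosome
  analyses iterate over per-chromosome tracks.
- The permutation test shuffles group labels of the assigned values;
  shuffling at the gene level (before max-assignment) is not implemented.
- No multiple-testing correction is applied across loci, matching the
  per-locus reporting convention of the analyses this package supports.
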