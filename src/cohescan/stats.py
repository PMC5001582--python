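"""Statistical tests and summaries for peak-derived vectors and FISH counts.

The workhorse comparison is the one-sided Wilcoxon rank-sum test between
the expression (or distance) vectors of two peak groups, verified by a
label-shuffling permutation test. Boxplot summaries follow the Tukey
1.5*IQR whisker rule with type-7 quartiles. FISH single/double-dot
proportions are compared either by a paired t-test across biological
replicates or, when only pooled counts are available, by a two-proportion
test (Fisher exact by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BoxplotSummary",
    "rank_sum_one_sided",
    "permutation_pvalue",
    "boxplot_summary",
    "two_proportion_test",
    "paired_t_test",
]

_SIDEDNESS = {"greater": "one_sided_greater", "less": "one_sided_less",
              "two-sided": "two_sided"}

#: sample-size bound below which the tie-free rank-sum distribution is
#: enumerated exactly rather than normal-approximated
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    sidedness: str
    n1: int
    n2: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[float, ...]


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(list(x), dtype=float)
    if v.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return v


def rank_sum_one_sided(x, y, alternative: str = "greater") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of x against y.

    ``alternative`` states the direction for x: "greater" tests whether x
    is stochastically larger than y. The exact null distribution is used
    for small tie-free samples (n1 + n2 <= 12); otherwise the normal
    approximation with tie and continuity corrections. The path taken is
    recorded in the result's method name.
    """
    if alternative not in _SIDEDNESS:
        raise ValueError(f"unknown alternative {alternative!r}")
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    pooled = np.concatenate([xv, yv])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; rank-sum p set to 1",
                      stacklevel=2)
        return TestResult(method="wilcoxon-ranksum-degenerate",
                          statistic=float(len(xv) * len(yv) / 2), p_value=1.0,
                          sidedness=_SIDEDNESS[alternative],
                          n1=len(xv), n2=len(yv))
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= EXACT_LIMIT) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(xv, yv, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult(
        method=f"wilcoxon-ranksum-{method}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=_SIDEDNESS[alternative],
        n1=len(xv), n2=len(yv),
    )


_STATISTICS = {
    "median_diff": lambda xs, ys: np.median(xs, axis=-1) - np.median(ys, axis=-1),
    "mean_diff": lambda xs, ys: np.mean(xs, axis=-1) - np.mean(ys, axis=-1),
    # sum of pooled ranks landing in the first group
    "rank_sum": None,  # handled specially on pre-computed ranks
}


def permutation_pvalue(x, y, statistic: str = "median_diff",
                       n_perm: int = 10000, seed: int = 0,
                       alternative: str = "greater",
                       chunk: int = 20000) -> TestResult:
    """Label-shuffling permutation test with the add-one p estimator.

    p = (1 + #{permuted statistic at least as extreme}) / (n_perm + 1),
    where "as extreme" follows ``alternative`` for x versus y.
    Reproducible for a fixed ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if alternative not in _SIDEDNESS:
        raise ValueError(f"unknown alternative {alternative!r}")
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    n1, n2 = len(xv), len(yv)
    pooled = np.concatenate([xv, yv])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled data; permutation p is 1", stacklevel=2)
        return TestResult(method=f"permutation-{statistic}", statistic=0.0,
                          p_value=1.0, sidedness=_SIDEDNESS[alternative],
                          n1=n1, n2=n2,
                          extra={"n_perm": n_perm, "seed": seed})
    if statistic == "rank_sum":
        data = sps.rankdata(pooled)
        stat_fn = lambda xs, ys: np.sum(xs, axis=-1)  # noqa: E731
    else:
        data = pooled
        stat_fn = _STATISTICS[statistic]
    observed = float(stat_fn(data[:n1], data[n1:]))
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    n = n1 + n2
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)
        perm = data[idx]
        stats_perm = stat_fn(perm[:, :n1], perm[:, n1:])
        if alternative == "greater":
            hits += int(np.sum(stats_perm >= observed))
        elif alternative == "less":
            hits += int(np.sum(stats_perm <= observed))
        else:
            # the rank-sum statistic is centred on its null mean; the
            # difference statistics are centred on 0 already
            center = n1 * (n + 1) / 2 if statistic == "rank_sum" else 0.0
            hits += int(np.sum(np.abs(stats_perm - center)
                               >= abs(observed - center)))
        done += m
    p = (1 + hits) / (n_perm + 1)
    return TestResult(method=f"permutation-{statistic}", statistic=observed,
                      p_value=p, sidedness=_SIDEDNESS[alternative],
                      n1=n1, n2=n2, extra={"n_perm": n_perm, "seed": seed})


def boxplot_summary(values) -> BoxplotSummary:
    """Tukey boxplot summary: type-7 quartiles, 1.5*IQR whisker rule.

    Whiskers extend to the adjacent values (the most extreme data inside
    the fences q1 - 1.5*IQR and q3 + 1.5*IQR); everything outside is an
    outlier.
    """
    v = _as_vector(values, "values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        lower_whisker=float(inside.min()),
        upper_whisker=float(inside.max()),
        outliers=tuple(sorted(float(o) for o in outliers)),
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int,
                        method: str = "fisher_exact") -> TestResult:
    """Two-sided test of H0: p1 == p2 on pooled counts.

    Fisher exact by default; ``method='z_pooled'`` uses the pooled-variance
    normal approximation. This is the surrogate applied to printed FISH
    single/double-dot totals when per-replicate values are unavailable.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    if method == "fisher_exact":
        odds, p = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                                   alternative="two-sided")
        stat = float(odds)
    elif method == "z_pooled":
        from statsmodels.stats.proportion import proportions_ztest
        stat_, p = proportions_ztest([k1, k2], [n1, n2],
                                     alternative="two-sided")
        stat = float(stat_)
        if np.isnan(p):  # both proportions 0 or both 1
            stat, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(method=f"two-proportion-{method}", statistic=stat,
                      p_value=float(min(p, 1.0)),
                      sidedness="two_sided", n1=n1, n2=n2)


def paired_t_test(a, b, alternative: str = "two-sided") -> TestResult:
    """Paired t-test across biological replicates (e.g. per-replicate FISH
    single-dot fractions under two conditions)."""
    if alternative not in _SIDEDNESS:
        raise ValueError(f"unknown alternative {alternative!r}")
    av = _as_vector(a, "a")
    bv = _as_vector(b, "b")
    if len(av) != len(bv):
        raise ValueError("paired samples must have equal length")
    if len(av) < 2:
        raise ValueError("paired t-test needs >= 2 replicates")
    res = sps.ttest_rel(av, bv, alternative=alternative)
    return TestResult(method="paired-t", statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      sidedness=_SIDEDNESS[alternative],
                      n1=len(av), n2=len(bv))
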