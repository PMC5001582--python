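import numpy as np
import pytest

from cohescan import (
    ClassifiedPeaks,
    assign_expression,
    distance_profile,
    expression_histogram,
    group_expression,
    margin_distance,
    nearest_peak_distance,
    normalize_to_wce,
    peak_signal_sums,
)
from cohescan.io_model import Gene, GeneSet, PeakSet

from conftest import make_pair_from_log2, peak, peak_set


class TestAssignExpression:
    def test_most_expressed_overlapping_gene_wins(self):
        genes = GeneSet([Gene("a", "chr2", 0, 1000, rpkm=10.0),
                         Gene("b", "chr2", 500, 1500, rpkm=600.0)])
        a = assign_expression(peak("chr2", 400, 1400), genes)
        assert a.assigned_rpkm == 600.0
        assert a.assigned_gene == "b"

    def test_no_overlapping_gene_is_missing(self):
        genes = GeneSet([Gene("a", "chr2", 0, 100, rpkm=10.0)])
        a = assign_expression(peak("chr2", 5000, 6000), genes)
        assert a.assigned_rpkm is None

    def test_zero_rpkm_beats_missing_rpkm(self):
        genes = GeneSet([Gene("a", "chr2", 0, 1000, rpkm=0.0),
                         Gene("b", "chr2", 0, 1000, rpkm=None)])
        a = assign_expression(peak("chr2", 100, 900), genes)
        assert a.assigned_rpkm == 0.0
        assert a.assigned_gene == "a"

    def test_equals_brute_force_max_and_gene_order_invariant(self):
        rng = np.random.default_rng(5)
        genes_list = [Gene(f"g{i}", "chr2", int(s), int(s) + 500,
                           rpkm=float(rng.uniform(0, 1000)))
                      for i, s in enumerate(rng.integers(0, 20_000, 40))]
        p = peak("chr2", 4000, 9000)
        expected = max((g.rpkm for g in genes_list
                        if g.start < p.end and p.start < g.end), default=None)
        for order in (genes_list, genes_list[::-1]):
            got = assign_expression(p, GeneSet(order)).assigned_rpkm
            assert got == expected


class TestGroupExpression:
    def _classified(self):
        pos = peak_set([(0, 1000), (2000, 3000)])
        neg = peak_set([(10_000, 11_000), (12_000, 13_000), (14_000, 15_000)],
                       label="Rad21-only")
        return ClassifiedPeaks(pos, neg, reference_label="Mis4")

    def test_vectors_with_missing_dropped(self):
        genes = GeneSet([
            Gene("a", "chr2", 0, 500, rpkm=600.0),
            Gene("b", "chr2", 2000, 2500, rpkm=900.0),
            Gene("c", "chr2", 10_000, 10_500, rpkm=10.0),
            Gene("d", "chr2", 12_000, 12_500, rpkm=20.0),
            # peak (14000,15000) overlaps nothing -> missing
        ])
        pos, neg = group_expression(self._classified(), genes)
        assert sorted(pos) == [600.0, 900.0]
        assert sorted(neg) == [10.0, 20.0]

    def test_one_empty_side_warns(self):
        genes = GeneSet([Gene("a", "chr2", 0, 500, rpkm=600.0)])
        with pytest.warns(UserWarning, match="negative"):
            pos, neg = group_expression(self._classified(), genes)
        assert len(neg) == 0

    def test_both_sides_empty_is_an_error(self):
        genes = GeneSet([Gene("a", "chr3", 0, 500, rpkm=600.0)])
        with pytest.raises(ValueError, match="no peak"):
            group_expression(self._classified(), genes)


class TestMarginDistance:
    def test_overlap_and_abutment_are_zero(self):
        assert margin_distance(peak("chr2", 100, 200), peak("chr2", 150, 250)) == 0
        assert margin_distance(peak("chr2", 100, 200), peak("chr2", 200, 300)) == 0

    def test_gap_between_margins(self):
        assert margin_distance(peak("chr2", 100, 200), peak("chr2", 500, 600)) == 300

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            margin_distance(peak("chr2", 0, 100), peak("chr3", 0, 100))

    def test_symmetry_and_triangle_bound_on_random_intervals(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            s = rng.integers(0, 10_000, size=3)
            a, b, c = (peak("chr2", int(x), int(x) + int(rng.integers(50, 500)))
                       for x in s)
            assert margin_distance(a, b) == margin_distance(b, a)
            assert margin_distance(a, b) <= (margin_distance(a, c)
                                             + (c.end - c.start)
                                             + margin_distance(c, b))


class TestNearestPeakDistance:
    def test_contained_peak_has_distance_zero(self):
        others = peak_set([(0, 10_000)], label="Pds5")
        assert nearest_peak_distance(peak("chr2", 2000, 3000), others) == 0

    def test_minimum_over_candidates(self):
        others = peak_set([(1500, 1600), (10_000, 10_100)], label="Pds5")
        assert nearest_peak_distance(peak("chr2", 100, 1200), others) == 300

    def test_no_candidate_on_chromosome_is_missing(self):
        others = peak_set([(0, 100)], chromosome="chr3", label="Pds5")
        with pytest.warns(UserWarning, match="distance is missing"):
            assert nearest_peak_distance(peak("chr2", 0, 100), others) is None


class TestDistanceProfile:
    def test_binning_and_normalization(self):
        prof = distance_profile([0, 1200, 7000], bin_width=5000)
        assert list(prof.counts) == [2, 1]
        assert prof.frequencies == pytest.approx([2 / 3, 1 / 3])

    def test_half_open_bin_edges(self):
        prof = distance_profile([4999, 5000], bin_width=5000)
        assert list(prof.counts) == [1, 1]

    def test_missing_values_stay_in_denominator(self):
        prof = distance_profile([0, 0, None, None], bin_width=5000)
        assert prof.frequencies[0] == pytest.approx(0.5)
        assert prof.n_missing == 2
        # frequencies sum to (non-missing)/(total) <= 1
        assert prof.frequencies.sum() == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_profile([], bin_width=5000)


class TestExpressionHistogram:
    def test_counts_per_group(self):
        out = expression_histogram({"A": [100, 700]}, [0, 600, 1200])
        assert list(out["A"]) == [1, 1]

    def test_interior_edge_goes_to_upper_bin(self):
        out = expression_histogram({"A": [600.0]}, [0, 600, 1200])
        assert list(out["A"]) == [0, 1]

    def test_empty_group_gives_zero_row(self):
        out = expression_histogram({"A": []}, [0, 600, 1200])
        assert list(out["A"]) == [0, 0]


class TestPeakSignalSums:
    def test_sum_of_probes_inside_peak(self):
        ip, wce = make_pair_from_log2([0.0, 0.5, 0.7, 0.0])
        track = normalize_to_wce(ip, wce)
        ps = PeakSet("Rad21", [peak("chr2", 250, 750, apex=250)])
        assert peak_signal_sums(ps, track) == [pytest.approx(1.2)]

    def test_fully_masked_peak_is_missing(self):
        ip, wce = make_pair_from_log2([0.0, None, None, 0.0])
        track = normalize_to_wce(ip, wce)
        ps = PeakSet("Rad21", [peak("chr2", 250, 750, apex=250)])
        with pytest.warns(UserWarning, match="no unmasked"):
            assert peak_signal_sums(ps, track) == [None]
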