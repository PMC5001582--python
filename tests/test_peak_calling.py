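import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohescan import (
    CallerConfig,
    call_peaks,
    default_config,
    extend_apex,
    filter_and_score,
    find_candidate_apexes,
    merge_candidate_intervals,
    normalize_to_wce,
)
from cohescan.io_model import AlignmentError
from cohescan.reference import reference_call_peaks

from conftest import make_pair_from_log2, make_track


def assert_matches_reference(peaks, ref):
    assert len(peaks) == len(ref)
    for g, r in zip(peaks, ref):
        assert (g.chromosome, g.start, g.end, g.apex_position, g.n_probes) == \
            (r[0], r[1], r[2], r[3], r[6])
        assert math.isclose(g.mean_log2, r[4], rel_tol=1e-9, abs_tol=1e-12)
        assert math.isclose(g.sum_log2, r[5], rel_tol=1e-9, abs_tol=1e-12)


class TestNormalizeToWce:
    def test_log2_ratio_and_masking(self):
        ip = make_track([4.0, 3.0, 0.0])
        wce = make_track([1.0, 3.0, 5.0], label="WCE")
        t = normalize_to_wce(ip, wce)
        assert t.values[0] == 2.0
        assert t.values[1] == 0.0
        assert list(t.mask) == [False, False, True]

    def test_grid_mismatch_reports_first_discrepancy(self):
        ip = make_track([1.0, 1.0], spacing=250)
        wce = make_track([1.0, 1.0], spacing=300, label="WCE")
        with pytest.raises(AlignmentError, match="250"):
            normalize_to_wce(ip, wce)


class TestFindCandidateApexes:
    def test_single_peak_above_threshold(self):
        ip, wce = make_pair_from_log2([0.0, 0.2, 0.8, 0.3, 0.0])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2)
        apexes = find_candidate_apexes(track, cfg)
        assert [a.index for a in apexes] == [2]

    def test_monotone_ramp_has_no_apex(self):
        ip, wce = make_pair_from_log2([0.0, 0.1, 0.2, 0.3])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.1, min_mean=0.0)
        assert find_candidate_apexes(track, cfg) == []

    def test_all_below_threshold_gives_empty(self):
        ip, wce = make_pair_from_log2([0.0, 0.2, 0.25, 0.1, 0.0])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2)
        assert find_candidate_apexes(track, cfg) == []

    def test_shallow_dip_keeps_only_higher_maximum(self):
        # two maxima separated by a dip of only 0.1 < sel
        ip, wce = make_pair_from_log2([0.0, 0.8, 0.7, 0.75, 0.0])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2, sel=0.2)
        assert [a.index for a in find_candidate_apexes(track, cfg)] == [1]

    def test_deep_dip_keeps_both_maxima(self):
        ip, wce = make_pair_from_log2([0.0, 0.8, 0.3, 0.75, 0.0])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2, sel=0.2)
        assert [a.index for a in find_candidate_apexes(track, cfg)] == [1, 3]

    def test_equal_height_tie_keeps_leftmost(self):
        ip, wce = make_pair_from_log2([0.0, 0.8, 0.7, 0.8, 0.0])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2, sel=0.2)
        assert [a.index for a in find_candidate_apexes(track, cfg)] == [1]


class TestExtendApex:
    def test_walk_stops_at_nonpositive_probe(self):
        ip, wce = make_pair_from_log2([-0.1, 0.4, 1.0, 0.6, 0.0, 0.3],
                                      spacing=500)
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2)
        apex = find_candidate_apexes(track, cfg)[0]
        # probes 1..3 stay above the floor; probe 4 (value 0.0) stops the walk
        assert extend_apex(track, apex, 0.0) == (500, 2000)

    def test_isolated_positive_probe_has_one_spacing_width(self):
        ip, wce = make_pair_from_log2([-0.1, 0.5, -0.2])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2)
        apex = find_candidate_apexes(track, cfg)
        # edge-adjacent plateau: probe 1 is a local max
        assert len(apex) == 1
        start, end = extend_apex(track, apex[0], 0.0)
        assert end - start == 250

    def test_extension_reaches_track_edge(self):
        ip, wce = make_pair_from_log2([0.4, 0.5, 1.0, 0.5, 0.4])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2)
        apex = find_candidate_apexes(track, cfg)[0]
        assert extend_apex(track, apex, 0.0) == (0, 4 * 250 + 250)

    def test_masked_probe_terminates_extension(self):
        ip, wce = make_pair_from_log2([0.4, None, 0.4, 1.0, 0.4])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2)
        apex = find_candidate_apexes(track, cfg)[0]
        start, _ = extend_apex(track, apex, 0.0)
        assert start == 500  # cannot cross the masked probe at 250


class TestMergeAndFilter:
    def test_merge_unions_overlaps_and_duplicates(self):
        assert merge_candidate_intervals(
            [(500, 2000), (1000, 2000), (500, 2000)]) == [(500, 2000)]
        assert merge_candidate_intervals(
            [(3000, 4000), (0, 1000)]) == [(0, 1000), (3000, 4000)]

    def test_scoring_arithmetic(self):
        ip, wce = make_pair_from_log2([-0.1, 0.4, 1.0, 0.6, 0.0, 0.3],
                                      spacing=500)
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2, min_width_bp=1000)
        ps = filter_and_score([(500, 2000)], track, cfg)
        assert len(ps) == 1
        p = ps.peaks[0]
        assert p.n_probes == 3
        assert math.isclose(p.sum_log2, 2.0)
        assert math.isclose(p.mean_log2, 2.0 / 3)
        assert p.apex_position == 1000
        assert p.width == 1500

    def test_narrow_interval_dropped(self):
        ip, wce = make_pair_from_log2([1.0, 1.0, 1.0])
        track = normalize_to_wce(ip, wce)
        cfg = CallerConfig(min_threshold=0.3, min_mean=0.2, min_width_bp=1000)
        assert len(filter_and_score([(0, 500)], track, cfg)) == 0

    def test_low_mean_interval_dropped_under_rad21_config(self):
        ip, wce = make_pair_from_log2([0.15, 0.15, 0.15, 0.15, 0.15])
        track = normalize_to_wce(ip, wce)
        assert len(filter_and_score([(0, 1250)], track,
                                    default_config("Rad21"))) == 0


class TestDefaultConfig:
    @pytest.mark.parametrize("label,threshold,min_mean", [
        ("Rad21", 0.3, 0.2),
        ("Swi6", 0.4, 0.3),
        ("Mis4", 0.5, 0.3),
        ("Sfc6", 0.5, 0.3),
        ("Pds5", 0.7, 0.4),
        ("Psc3", 0.7, 0.4),
        ("Ssl3", 0.7, 0.4),
        ("SomethingNew", 0.7, 0.4),
    ])
    def test_per_dataset_tiers(self, label, threshold, min_mean):
        cfg = default_config(label)
        assert cfg.min_threshold == threshold
        assert cfg.min_mean == min_mean
        assert cfg.sel == 0.2
        assert cfg.min_width_bp == 1000


class TestCallPeaks:
    def test_flat_zero_signal_yields_nothing(self):
        ip, wce = make_pair_from_log2([0.0] * 20)
        assert len(call_peaks(ip, wce, default_config("Rad21"))) == 0

    def test_single_planted_block_yields_one_peak(self):
        signal = [0.0] * 5 + [1.0] * 8 + [0.0] * 5
        ip, wce = make_pair_from_log2(signal)
        ps = call_peaks(ip, wce, default_config("Rad21"))
        assert len(ps) == 1
        p = ps.peaks[0]
        assert abs(p.start - 5 * 250) <= 250
        assert abs(p.end - 13 * 250) <= 250

    def test_blocks_separated_by_zero_gap_stay_apart(self):
        signal = [0.0] * 3 + [1.0] * 6 + [0.0] * 2 + [1.0] * 6 + [0.0] * 3
        ip, wce = make_pair_from_log2(signal)
        ps = call_peaks(ip, wce, default_config("Rad21"))
        assert len(ps) == 2

    def test_output_satisfies_caller_invariants(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(0, 0.5, 400)
        vals[100:130] += 1.2
        ip, wce = make_pair_from_log2(vals)
        cfg = default_config("Rad21")
        ps = call_peaks(ip, wce, cfg)
        track = normalize_to_wce(ip, wce)
        prev_end = -1
        for p in ps:
            assert p.start >= prev_end
            prev_end = p.end
            assert p.width >= cfg.min_width_bp
            assert p.mean_log2 >= cfg.min_mean
            inside = (track.positions > p.start) & (track.positions < p.end - 250)
            assert np.all(track.values[inside] > cfg.extension_floor)

    def test_translation_invariance(self):
        vals = [0.0, 0.3, 1.0, 0.9, 0.8, 0.2, 0.0, -0.1]
        ip0, wce0 = make_pair_from_log2(vals, start=0)
        ip1, wce1 = make_pair_from_log2(vals, start=7_000_000)
        cfg = default_config("Rad21")
        p0, p1 = call_peaks(ip0, wce0, cfg), call_peaks(ip1, wce1, cfg)
        assert len(p0) == len(p1) == 1
        assert p1.peaks[0].start - p0.peaks[0].start == 7_000_000
        assert p1.peaks[0].end - p0.peaks[0].end == 7_000_000

    @pytest.mark.parametrize("param,looser,tighter", [
        ("min_threshold", 0.3, 0.8),
        ("sel", 0.1, 0.6),
        ("min_width_bp", 500, 2500),
        ("min_mean", 0.1, 0.6),
    ])
    def test_tightening_any_filter_never_adds_peaks(self, param, looser, tighter):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.1, 0.6, 300)
        ip, wce = make_pair_from_log2(vals)
        base = dict(min_threshold=0.3, min_mean=0.2, sel=0.2, min_width_bp=1000)
        lo = dict(base, **{param: looser})
        hi = dict(base, **{param: tighter})
        n_loose = len(call_peaks(ip, wce, CallerConfig(**lo)))
        n_tight = len(call_peaks(ip, wce, CallerConfig(**hi)))
        assert n_tight <= n_loose


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(3, 50),
    threshold=st.sampled_from([0.3, 0.5, 0.7]),
    min_width=st.sampled_from([500, 1000]),
    mask_rate=st.sampled_from([0.0, 0.1]),
)
def test_caller_matches_naive_reference_on_random_tracks(
        seed, n, threshold, min_width, mask_rate):
    """The efficient caller and the loop-based reference must agree exactly."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 0.6, n)
    if rng.random() < 0.7:  # plant a bump so peaks are common
        a = int(rng.integers(0, n))
        vals[a:a + int(rng.integers(1, 9))] += rng.uniform(0.3, 1.5)
    ip, wce = make_pair_from_log2(vals)
    if mask_rate:
        bad = rng.random(n) < mask_rate
        ip.values[bad] = 0.0
    cfg = CallerConfig(min_threshold=threshold, min_mean=0.2,
                       min_width_bp=min_width)
    assert_matches_reference(call_peaks(ip, wce, cfg),
                             reference_call_peaks(ip, wce, cfg))
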