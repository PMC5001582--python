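"""The tiling-array peak caller.

The caller works on WCE-normalized log2 signal. Apexes are local maxima
that clear a per-dataset minimum height (``min_threshold``) and rise by at
least the selectivity ``sel`` above the surrounding signal; each apex is
extended in both directions until the log2 ratio drops to the extension
floor (0 by default, i.e. where the control channel overtakes the specific
signal); extended intervals are unioned and then filtered on width and
mean signal.

Apex selection is defined precisely as follows (masked probes split the
track into segments; within one segment):

1. A *candidate* is the leftmost index of a value plateau that is strictly
   higher than the adjacent differing values on both sides (segment edges
   therefore never qualify) and whose value is >= ``min_threshold``.
2. Candidates are visited in order of decreasing value (ties: leftmost
   first). A candidate is *accepted* if, between it and the nearest
   already-accepted candidate on each side (or the segment edge where none
   exists), the signal dips to at least ``sel`` below the candidate value.

Step 2 implements "the peak must be higher than the average surrounding
data by the cut-off factor": of two maxima not separated by a sufficient
dip only the higher survives, and a shoulder on the flank of a taller peak
is absorbed into it.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass

import numpy as np

from .io_model import (
    AlignmentError,
    CallerConfig,
    NormalizedTrack,
    Peak,
    PeakSet,
    ProbeTrack,
)

__all__ = [
    "CandidateApex",
    "default_config",
    "normalize_to_wce",
    "find_candidate_apexes",
    "extend_apex",
    "merge_candidate_intervals",
    "filter_and_score",
    "call_peaks",
]


@dataclass(frozen=True)
class CandidateApex:
    """An accepted apex probe: index into the track, position, log2 value."""

    index: int
    position: int
    value: float


# per-dataset (apex threshold, mean-signal filter); anything not listed
# falls into the default tier
_PARAM_TIERS: dict[str, tuple[float, float]] = {
    "rad21": (0.3, 0.2),
    "swi6": (0.4, 0.3),
    "mis4": (0.5, 0.3),
    "sfc6": (0.5, 0.3),
}
_DEFAULT_TIER = (0.7, 0.4)


def default_config(dataset_label: str) -> CallerConfig:
    """Per-dataset caller parameters.

    Rad21 -> threshold 0.3 / mean 0.2; Swi6 -> 0.4 / 0.3; Mis4 and Sfc6 ->
    0.5 / 0.3; every other dataset (Psc3, Pds5, Ssl3, no-tag, novel labels)
    -> 0.7 / 0.4. Selectivity 0.2 and minimum width 1000 bp throughout.
    """
    threshold, min_mean = _PARAM_TIERS.get(dataset_label.lower(), _DEFAULT_TIER)
    return CallerConfig(min_threshold=threshold, min_mean=min_mean)


def normalize_to_wce(ip: ProbeTrack, wce: ProbeTrack) -> NormalizedTrack:
    """Per-probe log2(IP/WCE); probes with a non-positive channel are masked."""
    if ip.chromosome != wce.chromosome:
        raise AlignmentError(
            f"chromosome mismatch: {ip.chromosome!r} vs {wce.chromosome!r}")
    if len(ip) != len(wce) or np.any(ip.positions != wce.positions):
        n = min(len(ip), len(wce))
        diff = np.flatnonzero(ip.positions[:n] != wce.positions[:n])
        where = (f"position {ip.positions[diff[0]]} vs {wce.positions[diff[0]]}"
                 if len(diff) else f"track lengths {len(ip)} vs {len(wce)}")
        raise AlignmentError(f"IP and WCE probe grids differ: first discrepancy {where}")
    mask = (ip.values <= 0) | (wce.values <= 0)
    values = np.zeros(len(ip), dtype=float)
    ok = ~mask
    values[ok] = np.log2(ip.values[ok] / wce.values[ok])
    return NormalizedTrack(
        chromosome=ip.chromosome,
        positions=ip.positions.copy(),
        values=values,
        dataset_label=ip.dataset_label,
        mask=mask,
    )


def _segments(mask: np.ndarray):
    """Yield (start, stop) index ranges of maximal unmasked runs, stop exclusive."""
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        yield i, j
        i = j


def _plateau_maxima(values: np.ndarray, a: int, b: int) -> list[int]:
    """Leftmost indices of interior value plateaus within values[a:b]."""
    out = []
    i = a
    while i < b:
        j = i
        while j + 1 < b and values[j + 1] == values[i]:
            j += 1
        interior = i > a and j < b - 1
        if interior and values[i - 1] < values[i] and values[j + 1] < values[i]:
            out.append(i)
        i = j + 1
    return out


def find_candidate_apexes(track: NormalizedTrack,
                          config: CallerConfig) -> list[CandidateApex]:
    """Accepted apexes over the whole track (see module docstring)."""
    if len(track) == 0:
        raise ValueError("track is empty")
    v = track.values
    result: list[int] = []
    for a, b in _segments(track.mask):
        cands = [i for i in _plateau_maxima(v, a, b)
                 if v[i] >= config.min_threshold]
        accepted: list[int] = []
        for c in sorted(cands, key=lambda i: (-v[i], i)):
            k = bisect.bisect_left(accepted, c)
            left = accepted[k - 1] if k > 0 else a
            right = accepted[k] if k < len(accepted) else b - 1
            if (v[c] - v[left:c + 1].min() >= config.sel
                    and v[c] - v[c:right + 1].min() >= config.sel):
                accepted.insert(k, c)
        result.extend(accepted)
    result.sort()
    return [CandidateApex(index=i, position=int(track.positions[i]),
                          value=float(v[i])) for i in result]


def extend_apex(track: NormalizedTrack, apex: CandidateApex,
                floor: float = 0.0) -> tuple[int, int]:
    """Extend an apex outward while the signal stays above ``floor``.

    Masked probes terminate extension. The interval is
    [position of first kept probe, position of last kept probe + spacing).
    """
    if apex.value <= floor:
        raise ValueError("apex value must exceed the extension floor")
    v, m = track.values, track.mask
    i = j = apex.index
    while i - 1 >= 0 and not m[i - 1] and v[i - 1] > floor:
        i -= 1
    while j + 1 < len(v) and not m[j + 1] and v[j + 1] > floor:
        j += 1
    return int(track.positions[i]), int(track.positions[j]) + track.spacing()


def merge_candidate_intervals(
        intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union overlapping or identical intervals; output sorted and disjoint."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def filter_and_score(intervals: list[tuple[int, int]], track: NormalizedTrack,
                     config: CallerConfig) -> PeakSet:
    """Apply the width and mean-signal filters and score surviving peaks.

    A peak's mean and sum use only unmasked probes inside its interval;
    the apex is the (leftmost) highest probe.
    """
    peaks: list[Peak] = []
    pos, v, m = track.positions, track.values, track.mask
    for start, end in intervals:
        inside = np.flatnonzero((pos >= start) & (pos < end) & ~m)
        if len(inside) == 0:
            warnings.warn(
                f"interval [{start},{end}) contains no unmasked probes; dropped",
                stacklevel=2)
            continue
        width = end - start
        vals = v[inside]
        mean = float(vals.mean())
        if width < config.min_width_bp or mean < config.min_mean:
            continue
        apex_i = inside[int(np.argmax(vals))]
        peaks.append(Peak(
            chromosome=track.chromosome,
            start=start,
            end=end,
            apex_position=int(pos[apex_i]),
            mean_log2=mean,
            sum_log2=float(vals.sum()),
            n_probes=len(inside),
        ))
    return PeakSet(dataset_label=track.dataset_label, peaks=peaks)


def call_peaks(ip: ProbeTrack, wce: ProbeTrack,
               config: CallerConfig | None = None) -> PeakSet:
    """Full caller: normalize, find apexes, extend, merge, filter, score."""
    if config is None:
        config = default_config(ip.dataset_label)
    track = normalize_to_wce(ip, wce)
    apexes = find_candidate_apexes(track, config)
    intervals = [extend_apex(track, a, config.extension_floor) for a in apexes]
    return filter_and_score(merge_candidate_intervals(intervals), track, config)
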