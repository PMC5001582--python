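"""Naive reference implementation of the peak caller, for validation.

This module re-implements the caller's semantics in deliberately plain,
loop-based Python, structured around maximal positive runs rather than
apex extension: every quantity (spacing, local maxima, dips, run bounds,
filters) is recomputed from first principles without sharing code with
:mod:`cohescan.peak_calling`. Tests and the acceptance harness compare the
production caller against this reference on random tracks; it is an
oracle, never a substitute for the caller.
"""

from __future__ import annotations

import math

__all__ = ["reference_call_peaks"]


def _median_gap(positions) -> int:
    if len(positions) < 2:
        return 1
    gaps = sorted(positions[i + 1] - positions[i] for i in range(len(positions) - 1))
    k = len(gaps)
    if k % 2 == 1:
        return int(gaps[k // 2])
    return int((gaps[k // 2 - 1] + gaps[k // 2]) / 2)


def _naive_local_maxima(v, lo, hi):
    """Leftmost plateau indices of interior local maxima of v[lo:hi]."""
    maxima = []
    for i in range(lo, hi):
        if i > lo and v[i - 1] == v[i]:
            continue  # not the leftmost index of its plateau
        # scan left to the first differing value
        j = i - 1
        while j >= lo and v[j] == v[i]:
            j -= 1
        if j < lo or v[j] >= v[i]:
            continue
        # scan right to the first differing value
        k = i + 1
        while k < hi and v[k] == v[i]:
            k += 1
        if k >= hi or v[k] >= v[i]:
            continue
        maxima.append(i)
    return maxima


def _naive_accept(v, lo, hi, candidates, sel):
    """Height-ordered greedy acceptance, recomputing every dip by loop."""
    order = sorted(candidates, key=lambda i: (-v[i], i))
    accepted = []
    for c in order:
        lefts = [a for a in accepted if a < c]
        rights = [a for a in accepted if a > c]
        left_bound = max(lefts) if lefts else lo
        right_bound = min(rights) if rights else hi - 1
        dip_left = min(v[left_bound:c + 1])
        dip_right = min(v[c:right_bound + 1])
        if v[c] - dip_left >= sel and v[c] - dip_right >= sel:
            accepted.append(c)
    return sorted(accepted)


def reference_call_peaks(ip, wce, config):
    """Call peaks the slow way; returns a list of plain tuples.

    Each tuple is (chromosome, start, end, apex_position, mean_log2,
    sum_log2, n_probes), sorted by start, for direct comparison with a
    :class:`~cohescan.io_model.PeakSet`.
    """
    assert ip.chromosome == wce.chromosome
    positions = [int(p) for p in ip.positions]
    assert positions == [int(p) for p in wce.positions]
    n = len(positions)
    values = [0.0] * n
    masked = [False] * n
    for i in range(n):
        a, b = float(ip.values[i]), float(wce.values[i])
        if a <= 0 or b <= 0:
            masked[i] = True
        else:
            values[i] = math.log2(a / b)
    spacing = _median_gap(positions)
    floor = config.extension_floor

    # maximal unmasked segments
    segments = []
    i = 0
    while i < n:
        if masked[i]:
            i += 1
            continue
        j = i
        while j < n and not masked[j]:
            j += 1
        segments.append((i, j))
        i = j

    peaks = []
    for lo, hi in segments:
        cands = [i for i in _naive_local_maxima(values, lo, hi)
                 if values[i] >= config.min_threshold]
        apexes = _naive_accept(values, lo, hi, cands, config.sel)
        # maximal runs of value > floor within the segment
        runs = []
        i = lo
        while i < hi:
            if values[i] <= floor:
                i += 1
                continue
            j = i
            while j < hi and values[j] > floor:
                j += 1
            runs.append((i, j))
            i = j
        for ri, rj in runs:
            run_apexes = [a for a in apexes if ri <= a < rj]
            if not run_apexes:
                continue
            start = positions[ri]
            end = positions[rj - 1] + spacing
            if end - start < config.min_width_bp:
                continue
            # peak content is defined by the position window, not the run
            inside = [i for i in range(n)
                      if start <= positions[i] < end and not masked[i]]
            vals = [values[i] for i in inside]
            total = sum(vals)
            mean = total / len(vals)
            if mean < config.min_mean:
                continue
            best = inside[0]
            for i in inside:
                if values[i] > values[best]:
                    best = i
            peaks.append((ip.chromosome, start, end, positions[best],
                          mean, total, len(vals)))
    peaks.sort(key=lambda t: t[1])
    return peaks
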