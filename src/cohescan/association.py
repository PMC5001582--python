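"""Linking classified peaks to gene expression and auxiliary-factor distances.

Expression is assigned to a peak as the RPKM of the most highly expressed
overlapping gene; peaks overlapping no gene of known expression carry a
missing assignment and are excluded from group comparisons. Distances
between peaks are margin distances (0 for any overlap) and are summarized
as binned profiles normalized to the size of the peak group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classification import ClassifiedPeaks
from .io_model import GeneSet, NormalizedTrack, Peak, PeakSet

__all__ = [
    "ExpressionAssignment",
    "DistanceProfile",
    "assign_expression",
    "group_expression",
    "margin_distance",
    "nearest_peak_distance",
    "distance_profile",
    "expression_histogram",
    "peak_signal_sums",
]


@dataclass(frozen=True)
class ExpressionAssignment:
    """The expression value a peak inherits from its overlapping genes."""

    peak: Peak
    assigned_rpkm: float | None
    assigned_gene: str | None


@dataclass
class DistanceProfile:
    """Binned distance counts normalized to the group size."""

    bin_width_bp: int
    counts: np.ndarray
    frequencies: np.ndarray
    n_total: int
    n_missing: int = 0
    source_label: str = ""
    target_label: str = ""


def assign_expression(peak: Peak, genes: GeneSet) -> ExpressionAssignment:
    """Max RPKM over genes overlapping the peak by >= 1 bp.

    Genes with unknown RPKM never win, even over RPKM 0; if no overlapping
    gene has a known RPKM the assignment is missing (such peaks are dropped
    from downstream expression comparisons).
    """
    best: tuple[float, str] | None = None
    for g in genes.overlapping(peak.chromosome, peak.start, peak.end):
        if g.rpkm is None:
            continue
        if best is None or g.rpkm > best[0]:
            best = (g.rpkm, g.identifier)
    if best is None:
        return ExpressionAssignment(peak=peak, assigned_rpkm=None,
                                    assigned_gene=None)
    return ExpressionAssignment(peak=peak, assigned_rpkm=best[0],
                                assigned_gene=best[1])


def group_expression(classified: ClassifiedPeaks,
                     genes: GeneSet) -> tuple[np.ndarray, np.ndarray]:
    """Assigned-RPKM vectors for the positive and negative peak groups.

    Missing assignments are dropped; an error is raised if both groups end
    up empty, a warning if only one does.
    """
    vectors = []
    for peak_set in (classified.positive_set, classified.negative_set):
        vals = [a.assigned_rpkm for a in
                (assign_expression(p, genes) for p in peak_set)
                if a.assigned_rpkm is not None]
        vectors.append(np.asarray(vals, dtype=float))
    pos, neg = vectors
    if len(pos) == 0 and len(neg) == 0:
        raise ValueError("no peak in either group overlaps a gene with known rpkm")
    if len(pos) == 0 or len(neg) == 0:
        empty = "positive" if len(pos) == 0 else "negative"
        warnings.warn(f"the {empty} group has no expression assignments",
                      stacklevel=2)
    return pos, neg


def margin_distance(a: Peak, b: Peak) -> int:
    """bp gap between annotated peak margins; any overlap counts as 0."""
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"margin distance undefined across chromosomes "
            f"({a.chromosome!r} vs {b.chromosome!r})")
    return max(0, a.start - b.end, b.start - a.end)


def nearest_peak_distance(peak: Peak, others: PeakSet) -> int | None:
    """Minimum margin distance to any same-chromosome peak; None if there is none."""
    candidates = others.on_chromosome(peak.chromosome)
    if not candidates:
        warnings.warn(
            f"no {others.dataset_label or 'target'} peak on {peak.chromosome}; "
            "distance is missing", stacklevel=2)
        return None
    return min(margin_distance(peak, o) for o in candidates)


def distance_profile(distances, bin_width: int = 5000,
                     dataset_size: int | None = None,
                     include_missing_in_denominator: bool = True,
                     source_label: str = "", target_label: str = "") -> DistanceProfile:
    """Bin distances into [k*w, (k+1)*w) and normalize to the group size.

    ``distances`` may contain None for peaks with no target on their
    chromosome; those never enter a bin but, by default, stay in the
    normalizing denominator ("size of the dataset under consideration").
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    distances = list(distances)
    if not distances:
        raise ValueError("cannot profile an empty distance list")
    present = [d for d in distances if d is not None]
    if any(d < 0 for d in present):
        raise ValueError("distances must be non-negative")
    n_missing = len(distances) - len(present)
    n_bins = (max(present) // bin_width + 1) if present else 1
    counts = np.zeros(n_bins, dtype=np.int64)
    for d in present:
        counts[d // bin_width] += 1
    if dataset_size is None:
        dataset_size = len(distances) if include_missing_in_denominator else len(present)
    denom = max(dataset_size, 1)
    return DistanceProfile(
        bin_width_bp=bin_width,
        counts=counts,
        frequencies=counts / denom,
        n_total=dataset_size,
        n_missing=n_missing,
        source_label=source_label,
        target_label=target_label,
    )


def expression_histogram(groups: dict[str, "np.ndarray | list"],
                         bin_edges) -> dict[str, np.ndarray]:
    """Per-group counts in half-open expression bins [e_i, e_{i+1}).

    A value on an interior edge falls in the upper bin; values outside
    [first edge, last edge) are not counted.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 entries")
    out: dict[str, np.ndarray] = {}
    for label, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
        if len(v):
            idx = np.searchsorted(edges, v, side="right") - 1
            ok = (idx >= 0) & (idx < len(counts)) & (v < edges[-1])
            np.add.at(counts, idx[ok], 1)
        out[label] = counts
    return out


def default_expression_bins(max_rpkm: float = 1500.0,
                            step: float = 150.0) -> np.ndarray:
    """Edges 0, step, ..., max_rpkm plus a wide final catch-all bin."""
    return np.append(np.arange(0.0, max_rpkm + step, step), np.inf)


def peak_signal_sums(peaks: PeakSet,
                     track: NormalizedTrack) -> list[float | None]:
    """Per-peak sum of unmasked log2 values within [start, end).

    None (with a warning) for a peak covering no unmasked probe.
    """
    pos, v, m = track.positions, track.values, track.mask
    sums: list[float | None] = []
    for p in peaks:
        if p.chromosome != track.chromosome:
            sums.append(None)
            continue
        inside = np.flatnonzero((pos >= p.start) & (pos < p.end) & ~m)
        if len(inside) == 0:
            warnings.warn(
                f"peak [{p.start},{p.end}) covers no unmasked probes",
                stacklevel=2)
            sums.append(None)
        else:
            sums.append(float(v[inside].sum()))
    return sums
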