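"""Partitioning cohesin peaks by loader co-localization and gene class.

A cohesin (e.g. Rad21) peak set is split against a reference set (e.g. the
loader Mis4): peaks overlapping a reference peak are the putative cohesive
sites, the remainder the non-cohesive ones. Peaks are further categorized
by whether they overlap RNAPII genes, RNAPIII genes (tRNA/5S rRNA), both
or neither, and can be split against an exclusion track such as Swi6
heterochromatin peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_model import Gene, GeneSet, Peak, PeakSet

__all__ = [
    "ClassifiedPeaks",
    "CategoryTable",
    "overlap_partition",
    "polymerase_category",
    "category_fractions",
    "exclusion_split",
    "pool_within",
]

CATEGORIES = ("RNAPII", "RNAPIII", "both", "none")


@dataclass
class ClassifiedPeaks:
    """Partition of a query peak set by reference overlap."""

    positive_set: PeakSet
    negative_set: PeakSet
    reference_label: str
    pad_bp: int = 0

    def __post_init__(self) -> None:
        if self.pad_bp < 0:
            raise ValueError("pad_bp must be >= 0")


@dataclass
class CategoryTable:
    """Counts and fractions of peaks per polymerase-overlap category."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n: int


def _intersects(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def overlap_partition(query: PeakSet, reference: PeakSet,
                      pad_bp: int = 0) -> ClassifiedPeaks:
    """Split query peaks by >= 1 bp overlap with any reference peak.

    Both query and reference intervals are extended by ``pad_bp`` at each
    end before testing (pad 0 for tiling-array sets; 200 for
    sequencing-derived sets, the estimated fragment size).
    """
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    positive, negative = [], []
    by_chrom: dict[str, list[Peak]] = {}
    for r in reference:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for q in query:
        hits = any(
            _intersects(q.start - pad_bp, q.end + pad_bp,
                        r.start - pad_bp, r.end + pad_bp)
            for r in by_chrom.get(q.chromosome, ()))
        (positive if hits else negative).append(q)
    return ClassifiedPeaks(
        positive_set=PeakSet(f"{query.dataset_label}+{reference.dataset_label}",
                             positive),
        negative_set=PeakSet(f"{query.dataset_label}-only", negative),
        reference_label=reference.dataset_label,
        pad_bp=pad_bp,
    )


def polymerase_category(peak: Peak, genes: GeneSet) -> str:
    """'RNAPII', 'RNAPIII', 'both' or 'none' by >= 1 bp gene overlap."""
    classes = {g.pol_class
               for g in genes.overlapping(peak.chromosome, peak.start, peak.end)}
    if classes == {"II"}:
        return "RNAPII"
    if classes == {"III"}:
        return "RNAPIII"
    if classes == {"II", "III"}:
        return "both"
    return "none"


def category_fractions(peaks: PeakSet, genes: GeneSet) -> CategoryTable:
    """Per-category counts and fractions over all peaks."""
    if len(peaks) == 0:
        raise ValueError("cannot compute category fractions of an empty peak set")
    counts = {c: 0 for c in CATEGORIES}
    for p in peaks:
        counts[polymerase_category(p, genes)] += 1
    n = len(peaks)
    return CategoryTable(counts=counts,
                         fractions={c: counts[c] / n for c in CATEGORIES},
                         n=n)


def exclusion_split(peaks: PeakSet,
                    exclusion: PeakSet) -> tuple[PeakSet, PeakSet]:
    """Split peaks into (overlapping, clear) against an exclusion track.

    Both subsets are returned so downstream statistics can be run with and
    without e.g. Swi6 heterochromatin or hyper-ChIPable regions.
    """
    part = overlap_partition(peaks, exclusion, pad_bp=0)
    overlapping = PeakSet(f"{peaks.dataset_label}/{exclusion.dataset_label}+",
                          list(part.positive_set))
    clear = PeakSet(f"{peaks.dataset_label}/{exclusion.dataset_label}-",
                    list(part.negative_set))
    return overlapping, clear


def pool_within(peaks: PeakSet, gap_bp: int) -> PeakSet:
    """Pool same-chromosome peaks separated by less than ``gap_bp``.

    Optional preprocessing (default off in all pipelines): pooled peaks
    take the union interval, summed signal, and the apex of the highest
    constituent.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    pooled: list[Peak] = []
    group: list[Peak] = []

    def _flush() -> None:
        if not group:
            return
        total = sum(p.sum_log2 for p in group)
        n = sum(p.n_probes for p in group)
        best = max(group, key=lambda p: p.mean_log2)
        pooled.append(Peak(
            chromosome=group[0].chromosome,
            start=group[0].start,
            end=max(p.end for p in group),
            apex_position=best.apex_position,
            mean_log2=total / n,
            sum_log2=total,
            n_probes=n,
        ))
        group.clear()

    for p in peaks:
        if (group and p.chromosome == group[-1].chromosome
                and p.start - group[-1].end < gap_bp):
            group.append(p)
        else:
            _flush()
            group.append(p)
    _flush()
    return PeakSet(f"{peaks.dataset_label}.pooled", pooled)
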