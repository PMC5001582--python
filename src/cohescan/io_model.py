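"""Domain types and file I/O for tiling-array cohesin analysis.

The analysis operates on probe-level ChIP-chip signal from a tiling array:
an immunoprecipitated (IP) channel and a whole-cell-extract (WCE) control
channel sampled on the same probe grid. All interval arithmetic downstream
uses 0-based half-open coordinates; GFF3 input (1-based inclusive) is
converted on read, BED is native.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeTrack",
    "NormalizedTrack",
    "CallerConfig",
    "Peak",
    "PeakSet",
    "Gene",
    "GeneSet",
    "OffsetMap",
    "FISHCounts",
    "read_probe_track",
    "read_gene_annotation",
    "attach_expression",
    "lift_coordinates",
    "write_peaks_bed",
    "read_peaks_bed",
]


class ParseError(ValueError):
    """A malformed input line; the message names the offending line number."""


class AlignmentError(ValueError):
    """Two probe tracks that should share a grid do not."""


# --------------------------------------------------------------------------
# probe-level signal


@dataclass
class ProbeTrack:
    """Ordered probe positions with one signal channel on one chromosome."""

    chromosome: str
    positions: np.ndarray
    values: np.ndarray
    dataset_label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be 1-D arrays of equal length")
        if len(self.positions) and self.positions.min() < 0:
            raise ValueError("probe positions must be non-negative")
        if len(self.positions) > 1:
            diffs = np.diff(self.positions)
            if np.any(diffs <= 0):
                i = int(np.argmax(diffs <= 0))
                raise ValueError(
                    f"probe positions must be strictly increasing; "
                    f"violation at position {self.positions[i + 1]}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def spacing(self) -> int:
        """Inferred probe spacing: the median inter-probe gap (1 if <2 probes)."""
        if len(self.positions) < 2:
            return 1
        return int(np.median(np.diff(self.positions)))


@dataclass
class NormalizedTrack(ProbeTrack):
    """log2(IP/WCE) per probe; probes where the ratio is undefined are masked."""

    mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.positions.shape:
            raise ValueError("mask must have one flag per probe")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("unmasked normalized values must be finite")


# --------------------------------------------------------------------------
# peak caller configuration and called peaks


@dataclass(frozen=True)
class CallerConfig:
    """Tunable parameters of the peak caller.

    ``min_threshold`` is the minimum log2 apex height, ``sel`` the factor by
    which an apex must rise above the surrounding signal, ``min_width_bp``
    and ``min_mean`` the post-hoc width and mean-signal filters, and
    ``extension_floor`` the log2 level down to which peaks are extended.
    """

    min_threshold: float
    min_mean: float
    sel: float = 0.2
    min_width_bp: int = 1000
    extension_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.min_threshold <= 0:
            raise ValueError("min_threshold must be > 0")
        if self.sel <= 0:
            raise ValueError("sel must be > 0")
        if self.min_width_bp <= 0:
            raise ValueError("min_width_bp must be > 0")


@dataclass(frozen=True)
class Peak:
    """A called enriched interval (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    apex_position: int
    mean_log2: float
    sum_log2: float
    n_probes: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak start must be < end")
        if not (self.start <= self.apex_position < self.end):
            raise ValueError("apex must lie within the peak interval")
        if self.n_probes < 1:
            raise ValueError("a peak must contain at least one probe")
        if not np.isclose(self.mean_log2, self.sum_log2 / self.n_probes,
                          rtol=1e-9, atol=1e-12):
            raise ValueError("mean_log2 must equal sum_log2 / n_probes")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """Sorted, per-chromosome non-overlapping peaks from one dataset."""

    dataset_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chromosome, p.start))
        prev: Peak | None = None
        for p in self.peaks:
            if prev is not None and prev.chromosome == p.chromosome and p.start < prev.end:
                raise ValueError(
                    f"peaks overlap on {p.chromosome}: "
                    f"[{prev.start},{prev.end}) and [{p.start},{p.end})"
                )
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def on_chromosome(self, chromosome: str) -> list[Peak]:
        return [p for p in self.peaks if p.chromosome == chromosome]


# --------------------------------------------------------------------------
# genes


@dataclass(frozen=True)
class Gene:
    """A gene interval tagged with its transcribing polymerase class."""

    identifier: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    pol_class: str = "II"
    rpkm: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("gene start must be < end")
        if self.pol_class not in ("II", "III"):
            raise ValueError("pol_class must be 'II' or 'III'")
        if self.rpkm is not None and self.rpkm < 0:
            raise ValueError("rpkm must be non-negative")


class GeneSet:
    """Genes sorted by (chromosome, start) with interval overlap lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chromosome, g.start))
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[Gene]]] = {}
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, gs in by_chrom.items():
            starts = np.array([g.start for g in gs], dtype=np.int64)
            ends = np.array([g.end for g in gs], dtype=np.int64)
            self._index[chrom] = (starts, ends, gs)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def overlapping(self, chromosome: str, start: int, end: int) -> list[Gene]:
        """Genes intersecting [start, end) by >= 1 bp."""
        if chromosome not in self._index:
            return []
        starts, ends, gs = self._index[chromosome]
        hits = np.flatnonzero((starts < end) & (ends > start))
        return [gs[i] for i in hits]


# --------------------------------------------------------------------------
# coordinate adjustment

#: per-chromosome list of (breakpoint, cumulative offset); the offset applies
#: to every position >= its breakpoint.
OffsetMap = Mapping[str, Sequence[tuple[int, int]]]


def lift_coordinates(positions: Sequence[int], offsets: OffsetMap,
                     chromosome: str) -> np.ndarray:
    """Shift coordinates by a piecewise-constant offset map.

    Used to reconcile legacy array coordinates with the current genome
    annotation (e.g. an 80,031-bp shift on chromosome 2). Positions before
    the first breakpoint, or on chromosomes absent from the map, are
    returned unchanged.
    """
    pos = np.asarray(positions, dtype=np.int64)
    segments = list(offsets.get(chromosome, ()))
    if not segments:
        return pos.copy()
    breaks = np.array([b for b, _ in segments], dtype=np.int64)
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("offset breakpoints must be strictly increasing")
    shift = np.array([o for _, o in segments], dtype=np.int64)
    idx = np.searchsorted(breaks, pos, side="right") - 1
    out = pos.copy()
    applies = idx >= 0
    out[applies] += shift[idx[applies]]
    return out


# --------------------------------------------------------------------------
# FISH dot counts


@dataclass(frozen=True)
class FISHCounts:
    """Single- vs double-dot cell counts for one locus under one condition."""

    locus: str
    condition: str
    n_single: int
    n_double: int

    def __post_init__(self) -> None:
        if self.n_single < 0 or self.n_double < 0:
            raise ValueError("dot counts must be non-negative")
        if self.n_single + self.n_double == 0:
            raise ValueError("at least one cell must be counted")

    @property
    def n_cells(self) -> int:
        return self.n_single + self.n_double

    @property
    def fraction_single(self) -> float:
        return self.n_single / self.n_cells


# --------------------------------------------------------------------------
# readers / writers


def read_probe_track(path, dataset_label: str = "") -> ProbeTrack:
    """Read a tab-delimited probe table (chromosome, position, value).

    Lines starting with '#' are comments. Rows need not be sorted; the
    returned track is sorted by position. Duplicate positions and files
    spanning more than one chromosome are errors.
    """
    chroms: list[str] = []
    positions: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                pos = int(fields[1])
                val = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            chroms.append(fields[0])
            positions.append(pos)
            values.append(val)
    if not positions:
        raise ParseError(f"{path}: no probe rows found")
    if len(set(chroms)) > 1:
        raise ValueError(f"{path}: a probe track must cover a single chromosome")
    order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable")
    pos_arr = np.asarray(positions, dtype=np.int64)[order]
    dup = np.flatnonzero(np.diff(pos_arr) == 0)
    if len(dup):
        raise ValueError(f"{path}: duplicate probe position {pos_arr[dup[0]]}")
    return ProbeTrack(
        chromosome=chroms[0],
        positions=pos_arr,
        values=np.asarray(values, dtype=float)[order],
        dataset_label=dataset_label,
    )


_DEFAULT_POL3_TYPES = frozenset({"tRNA", "tRNA_gene", "rRNA_5S", "5S_rRNA"})

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]


def _gff_attribute(attrs: str, key: str) -> str | None:
    m = re.search(rf"(?:^|;)\s*{key}=([^;]+)", attrs)
    return m.group(1).strip() if m else None


def read_gene_annotation(path, pol3_types: Iterable[str] | None = None) -> GeneSet:
    """Read gene intervals from GFF3 or BED (auto-detected by extension).

    Every feature row becomes one gene. Rows whose feature type is in
    ``pol3_types`` (default: tRNA and 5S rRNA types) are tagged RNAPIII;
    all others are assumed RNAPII transcribed. GFF3 coordinates are
    converted to 0-based half-open.
    """
    p3 = frozenset(pol3_types) if pol3_types is not None else _DEFAULT_POL3_TYPES
    spath = str(path)
    lower = spath.lower()
    if lower.endswith((".gff", ".gff3")):
        df = pd.read_csv(spath, sep="\t", comment="#", header=None,
                         names=_GFF_COLS, dtype={"seqid": str})
        genes = []
        for i, row in enumerate(df.itertuples(index=False)):
            ident = (_gff_attribute(str(row.attributes), "ID")
                     or _gff_attribute(str(row.attributes), "Name")
                     or f"feature{i + 1}")
            genes.append(Gene(
                identifier=ident,
                chromosome=row.seqid,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=str(row.strand) if str(row.strand) in "+-" else ".",
                pol_class="III" if str(row.type) in p3 else "II",
            ))
        return GeneSet(genes)
    if lower.endswith(".bed"):
        df = pd.read_csv(spath, sep="\t", comment="#", header=None, dtype={0: str})
        genes = []
        for i, row in enumerate(df.itertuples(index=False)):
            row = tuple(row)
            name = str(row[3]) if len(row) > 3 else f"feature{i + 1}"
            strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "."
            ftype = str(row[6]) if len(row) > 6 else ""
            genes.append(Gene(
                identifier=name,
                chromosome=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=strand,
                pol_class="III" if ftype in p3 else "II",
            ))
        return GeneSet(genes)
    raise ValueError(f"unknown annotation format for {spath!r} "
                     "(expected .gff/.gff3 or .bed)")


def attach_expression(genes: GeneSet, rpkm_table: Mapping[str, float]) -> GeneSet:
    """Attach per-gene RPKM values; genes absent from the table stay missing.

    Table entries without a matching gene are reported as warnings.
    """
    for gid, value in rpkm_table.items():
        if value < 0:
            raise ValueError(f"negative rpkm for gene {gid!r}")
    known = {g.identifier for g in genes}
    orphans = sorted(set(rpkm_table) - known)
    if orphans:
        warnings.warn(
            f"{len(orphans)} rpkm table entries match no gene "
            f"(first: {orphans[0]!r})", stacklevel=2)
    out = [replace(g, rpkm=float(rpkm_table[g.identifier]))
           if g.identifier in rpkm_table else g
           for g in genes]
    return GeneSet(out)


def read_rpkm_table(path) -> dict[str, float]:
    """Read a two-column (gene id, rpkm) tab-delimited table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "rpkm"], dtype={"gene": str})
    return dict(zip(df["gene"], df["rpkm"].astype(float)))


def write_peaks_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED6+ with mean/sum/apex/n_probes extra columns.

    Score is round(1000 * mean_log2) clipped to [0, 1000].
    """
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            score = int(np.clip(round(1000 * p.mean_log2), 0, 1000))
            name = f"{peaks.dataset_label or 'peak'}.{i}"
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\t{name}\t{score}\t.\t"
                f"{p.mean_log2!r}\t{p.sum_log2!r}\t{p.apex_position}\t"
                f"{p.n_probes}\n"
            )


def read_peaks_bed(path, dataset_label: str | None = None) -> PeakSet:
    """Read a BED6+ peak file written by :func:`write_peaks_bed`."""
    label = dataset_label
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 10 BED6+ fields")
            if label is None:
                label = fields[3].rsplit(".", 1)[0]
            peaks.append(Peak(
                chromosome=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                apex_position=int(fields[8]),
                mean_log2=float(fields[6]),
                sum_log2=float(fields[7]),
                n_probes=int(fields[9]),
            ))
    return PeakSet(dataset_label=label or "", peaks=peaks)
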