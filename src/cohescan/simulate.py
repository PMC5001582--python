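"""Synthetic tiling-array data with known truth, for testing every stage.

The generator emulates the structure the analysis assumes: a probe grid at
fixed spacing on one chromosome; rectangular (optionally shouldered)
enriched regions planted per dataset in log2 space; multiplicative
log-normal noise on the IP and WCE channels; gene models tagged RNAPII or
RNAPIII whose expression is drawn from a high log-normal stratum at
cohesive sites and a low stratum elsewhere; and binomial FISH dot counts.

Default condition mirrors the chromosome-2 analysis scale: 250-bp probe
spacing, planted height 1.0 log2 units, width 2000 bp, noise_sd 0.15, 283
cohesin and 150 loader peaks on 4.5 Mb with a cohesive fraction of 0.33
(one peak per ~16 kb). ``landscape_config`` keeps that per-peak density
when the peak count is scaled down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import FISHCounts, Gene, GeneSet, PeakSet, ProbeTrack

__all__ = [
    "PlantedPeak",
    "SimulationConfig",
    "TruthSet",
    "RecoveryMetrics",
    "landscape_config",
    "simulate_tracks",
    "simulate_genes",
    "simulate_fish_counts",
    "score_recovery",
]

#: genomic bp per planted cohesin peak at the chromosome-2-scale default
#: (283 peaks over a 4.5-Mb chromosome arm)
PEAK_DENSITY_BP = 16_000


@dataclass(frozen=True)
class PlantedPeak:
    start: int
    end: int
    height: float  # log2 enrichment over background
    shoulder_bp: int = 0  # linear decay flank on each side; 0 = rectangular

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("planted peak start must be < end")
        if self.height <= 0:
            raise ValueError("planted height must be > 0")
        if self.shoulder_bp < 0:
            raise ValueError("shoulder_bp must be >= 0")


@dataclass
class SimulationConfig:
    genome_length: int = 4_500_000
    chromosome: str = "chr2"
    probe_spacing: int = 250
    datasets: dict[str, list[PlantedPeak]] = field(default_factory=dict)
    noise_sd: float = 0.15  # sd of log2 multiplicative noise, both channels
    wce_baseline: float = 100.0  # mean WCE intensity
    seed: int = 0
    # gene model
    n_genes: int | None = None  # default: one gene per 3 kb
    fraction_pol3: float = 0.04
    gene_length_bp: int = 1500
    # expression model (log-normal strata, RPKM)
    high_median_rpkm: float = 700.0
    low_median_rpkm: float = 50.0
    rpkm_sigma_log: float = 1.0
    cohesive_fraction: float = 0.33

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.cohesive_fraction <= 1.0:
            raise ValueError("cohesive_fraction must be in [0, 1]")
        for label, planted in self.datasets.items():
            for pk in planted:
                if pk.start < 0 or pk.end > self.genome_length:
                    raise ValueError(
                        f"planted peak [{pk.start},{pk.end}) of {label!r} "
                        f"outside the {self.genome_length}-bp genome")


@dataclass
class TruthSet:
    """Planted intervals per dataset, true gene expression, cohesive pairing."""

    planted: dict[str, list[PlantedPeak]]
    cohesive_pairs: list[tuple[PlantedPeak, PlantedPeak]] = field(default_factory=list)
    gene_rpkm: dict[str, float] = field(default_factory=dict)
    gene_stratum: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RecoveryMetrics:
    recall: float
    precision: float
    mean_boundary_error_bp: float
    n_truth: int
    n_called: int


def landscape_config(n_query_peaks: int = 283, n_reference_peaks: int = 150,
                     cohesive_fraction: float = 0.33,
                     query_label: str = "Rad21", reference_label: str = "Mis4",
                     peak_width_bp: int = 2000, peak_height: float = 1.0,
                     noise_sd: float = 0.15, probe_spacing: int = 250,
                     shoulder_bp: int = 0, seed: int = 0,
                     genome_length: int | None = None) -> SimulationConfig:
    """A two-dataset cohesin/loader landscape with a known cohesive fraction.

    ``cohesive_fraction`` of the query (cohesin) peaks are co-planted with a
    reference (loader) peak at the same location; the remaining reference
    peaks are planted away from every query peak. Unless given, the genome
    length keeps one query peak per ~16 kb.
    """
    if genome_length is None:
        genome_length = max(n_query_peaks, 1) * PEAK_DENSITY_BP
    rng = np.random.default_rng(seed)
    n_shared = int(round(cohesive_fraction * n_query_peaks))
    n_shared = min(n_shared, n_reference_peaks)
    n_ref_only = n_reference_peaks - n_shared
    n_slots = n_query_peaks + n_ref_only
    # non-overlapping slots with at least one slot-width of clear flank
    slot = 2 * (peak_width_bp + 2 * shoulder_bp)
    if n_slots * slot > genome_length:
        raise ValueError("genome too short for the requested peak count")
    starts = (np.sort(rng.choice(genome_length // slot, size=n_slots,
                                 replace=False)) * slot
              + slot // 4)
    rng.shuffle(starts)
    query, reference, pairs = [], [], []
    for i in range(n_query_peaks):
        s = int(starts[i])
        qpk = PlantedPeak(s, s + peak_width_bp, peak_height, shoulder_bp)
        query.append(qpk)
        if i < n_shared:
            rpk = PlantedPeak(s, s + peak_width_bp, peak_height, shoulder_bp)
            reference.append(rpk)
            pairs.append((qpk, rpk))
    for i in range(n_query_peaks, n_slots):
        s = int(starts[i])
        reference.append(PlantedPeak(s, s + peak_width_bp, peak_height,
                                     shoulder_bp))
    cfg = SimulationConfig(
        genome_length=genome_length,
        probe_spacing=probe_spacing,
        datasets={query_label: sorted(query, key=lambda p: p.start),
                  reference_label: sorted(reference, key=lambda p: p.start)},
        noise_sd=noise_sd,
        cohesive_fraction=cohesive_fraction,
        seed=seed,
    )
    cfg._pairs = pairs  # type: ignore[attr-defined]
    return cfg


def _planted_height(positions: np.ndarray,
                    planted: list[PlantedPeak]) -> np.ndarray:
    h = np.zeros(len(positions), dtype=float)
    for pk in planted:
        core = (positions >= pk.start) & (positions < pk.end)
        h[core] = np.maximum(h[core], pk.height)
        if pk.shoulder_bp > 0:
            left = (positions >= pk.start - pk.shoulder_bp) & (positions < pk.start)
            h[left] = np.maximum(
                h[left],
                pk.height * (1 - (pk.start - positions[left]) / pk.shoulder_bp))
            right = (positions >= pk.end) & (positions < pk.end + pk.shoulder_bp)
            h[right] = np.maximum(
                h[right],
                pk.height * (1 - (positions[right] - pk.end + 1) / pk.shoulder_bp))
    return h


def simulate_tracks(config: SimulationConfig
                    ) -> tuple[dict[str, tuple[ProbeTrack, ProbeTrack]], TruthSet]:
    """IP/WCE probe-track pairs per dataset plus the planted truth.

    WCE is a positive baseline with multiplicative log-normal noise;
    IP = WCE * 2**(h(x) + eps) with h the planted log2 height and
    eps ~ Normal(0, noise_sd). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    positions = np.arange(0, config.genome_length, config.probe_spacing,
                          dtype=np.int64)
    out: dict[str, tuple[ProbeTrack, ProbeTrack]] = {}
    for label in sorted(config.datasets):
        planted = config.datasets[label]
        h = _planted_height(positions, planted)
        eta = rng.normal(0.0, config.noise_sd, len(positions))
        eps = rng.normal(0.0, config.noise_sd, len(positions))
        wce_vals = config.wce_baseline * np.exp2(eta)
        ip_vals = wce_vals * np.exp2(h + eps)
        wce = ProbeTrack(config.chromosome, positions.copy(), wce_vals,
                         dataset_label="WCE")
        ip = ProbeTrack(config.chromosome, positions.copy(), ip_vals,
                        dataset_label=label)
        out[label] = (ip, wce)
    truth = TruthSet(planted={k: list(v) for k, v in config.datasets.items()},
                     cohesive_pairs=list(getattr(config, "_pairs", [])))
    return out, truth


def simulate_genes(config: SimulationConfig, truth: TruthSet,
                   query_label: str | None = None) -> GeneSet:
    """Gene models whose expression encodes the cohesive/non-cohesive contrast.

    One gene is centred on every planted query-dataset peak; genes at peaks
    that are cohesive (paired with a reference peak in the truth) draw RPKM
    from the high log-normal stratum, all other genes from the low stratum.
    Background genes fill the remaining genome up to ``n_genes``; a
    ``fraction_pol3`` of background genes is tagged RNAPIII. The true
    stratum of every gene is recorded in the truth set.
    """
    rng = np.random.default_rng(config.seed + 1)
    if query_label is None:
        query_label = sorted(truth.planted)[0] if truth.planted else None
    planted = truth.planted.get(query_label, []) if query_label else []
    cohesive_starts = {pair[0].start for pair in truth.cohesive_pairs}

    genes: list[Gene] = []
    occupied: list[tuple[int, int]] = []

    def _rpkm(stratum: str) -> float:
        median = (config.high_median_rpkm if stratum == "high"
                  else config.low_median_rpkm)
        return float(median * np.exp(rng.normal(0.0, config.rpkm_sigma_log)))

    gid = 0
    for pk in sorted(planted, key=lambda p: p.start):
        gid += 1
        stratum = "high" if pk.start in cohesive_starts else "low"
        center = (pk.start + pk.end) // 2
        half = config.gene_length_bp // 2
        start = max(0, center - half)
        end = min(config.genome_length, center + half)
        name = f"gene{gid:05d}"
        genes.append(Gene(name, config.chromosome, start, end,
                          strand="+" if rng.random() < 0.5 else "-",
                          pol_class="II", rpkm=_rpkm(stratum)))
        truth.gene_rpkm[name] = genes[-1].rpkm
        truth.gene_stratum[name] = stratum
        occupied.append((start, end))

    n_genes = (config.n_genes if config.n_genes is not None
               else config.genome_length // 3000)
    n_background = max(0, n_genes - len(genes))
    occupied.sort()
    placed = 0
    attempts = 0
    while placed < n_background and attempts < 50 * max(n_background, 1):
        attempts += 1
        start = int(rng.integers(0, max(1, config.genome_length
                                        - config.gene_length_bp)))
        end = start + config.gene_length_bp
        if any(s < end and start < e for s, e in occupied):
            continue
        gid += 1
        placed += 1
        name = f"gene{gid:05d}"
        pol = "III" if rng.random() < config.fraction_pol3 else "II"
        genes.append(Gene(name, config.chromosome, start, end,
                          strand="+" if rng.random() < 0.5 else "-",
                          pol_class=pol, rpkm=_rpkm("low")))
        truth.gene_rpkm[name] = genes[-1].rpkm
        truth.gene_stratum[name] = "low"
        occupied.append((start, end))
        occupied.sort()
    return GeneSet(genes)


def simulate_fish_counts(p_single: float, n_cells: int, n_replicates: int,
                         seed: int = 0, locus: str = "CAR",
                         condition: str = "") -> list[FISHCounts]:
    """Per-replicate binomial single/double dot counts."""
    if not 0.0 <= p_single <= 1.0:
        raise ValueError("p_single must be a probability")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        n_single = int(rng.binomial(n_cells, p_single))
        out.append(FISHCounts(locus=locus, condition=condition or f"rep{r + 1}",
                              n_single=n_single, n_double=n_cells - n_single))
    return out


def score_recovery(called: PeakSet, truth_intervals,
                   tolerance_bp: int = 0) -> RecoveryMetrics:
    """Recall/precision/boundary error of called peaks against planted truth.

    A truth interval counts as recovered if a called peak overlaps it after
    expanding the truth by ``tolerance_bp`` on each side; precision is the
    fraction of called peaks matching any (expanded) truth interval.
    Boundary error averages |called margin - truth margin| over matched
    pairs (nearest truth interval per called peak).
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    truths = [(t.start, t.end) if isinstance(t, PlantedPeak) else (t[0], t[1])
              for t in truth_intervals]
    calls = [(p.start, p.end) for p in called]
    n_truth, n_called = len(truths), len(calls)

    def _overlaps(c, t):
        return c[0] < t[1] + tolerance_bp and t[0] - tolerance_bp < c[1]

    recovered = sum(any(_overlaps(c, t) for c in calls) for t in truths)
    matched_calls = [c for c in calls if any(_overlaps(c, t) for t in truths)]
    errors = []
    for c in matched_calls:
        t = min((t for t in truths if _overlaps(c, t)),
                key=lambda t: abs(c[0] - t[0]) + abs(c[1] - t[1]))
        errors.append((abs(c[0] - t[0]) + abs(c[1] - t[1])) / 2)
    return RecoveryMetrics(
        recall=recovered / n_truth if n_truth else 1.0,
        precision=len(matched_calls) / n_called if n_called else 1.0,
        mean_boundary_error_bp=float(np.mean(errors)) if errors else 0.0,
        n_truth=n_truth,
        n_called=n_called,
    )
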