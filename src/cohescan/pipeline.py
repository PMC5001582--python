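"""End-to-end analysis: peaks -> classification -> expression -> statistics.

``run_full_analysis`` composes all stages for a configured set of probe
tracks: call peaks per dataset, partition the cohesin peaks by each loader
set, categorize against gene annotation, assign expression, compute
distance profiles to auxiliary factors, run the rank-sum and permutation
tests, optionally repeat the expression comparison after excluding an
exclusion track (e.g. Swi6), and write BED/TSV outputs plus a
machine-readable JSON summary and a parameter log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, classification, peak_calling
from .io_model import (
    CallerConfig,
    GeneSet,
    PeakSet,
    attach_expression,
    read_gene_annotation,
    read_probe_track,
    read_rpkm_table,
    write_peaks_bed,
)

__all__ = ["PipelineConfig", "run_full_analysis", "load_pipeline_config"]

log = logging.getLogger("cohescan.pipeline")


@dataclass
class PipelineConfig:
    #: dataset label -> {"ip": path, "wce": path}
    tracks: dict[str, dict[str, str]]
    genes_path: str
    output_dir: str
    rpkm_path: str | None = None
    query_dataset: str = "Rad21"
    reference_datasets: list[str] = field(default_factory=lambda: ["Mis4"])
    distance_datasets: list[str] = field(default_factory=list)
    exclusion_dataset: str | None = None
    caller_overrides: dict[str, dict] = field(default_factory=dict)
    pad_bp: int = 0
    bin_width_bp: int = 5000
    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.query_dataset not in self.tracks:
            raise ValueError(
                f"query dataset {self.query_dataset!r} has no tracks configured")
        for ref in self.reference_datasets:
            if ref not in self.tracks:
                raise ValueError(f"reference dataset {ref!r} has no tracks")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _caller_config(label: str, overrides: dict[str, dict]) -> CallerConfig:
    base = peak_calling.default_config(label)
    ov = overrides.get(label, {})
    if not ov:
        return base
    params = asdict(base)
    params.update(ov)
    return CallerConfig(**params)


def _stage(name: str):
    log.info("stage: %s", name)


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    from . import stats as st

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = outdir / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"parameters": {
        "pad_bp": config.pad_bp,
        "bin_width_bp": config.bin_width_bp,
        "n_perm": config.n_perm,
        "seed": config.seed,
    }}
    try:
        # ---- peak calling per dataset
        peak_sets: dict[str, PeakSet] = {}
        tracks_norm = {}
        for label, paths in config.tracks.items():
            _stage(f"call peaks: {label}")
            for key in ("ip", "wce"):
                if key not in paths or not Path(paths[key]).exists():
                    raise FileNotFoundError(
                        f"stage 'call peaks ({label})': missing {key} track "
                        f"{paths.get(key)!r}")
            ip = read_probe_track(paths["ip"], dataset_label=label)
            wce = read_probe_track(paths["wce"], dataset_label="WCE")
            cc = _caller_config(label, config.caller_overrides)
            log.info("caller config %s: %s", label, cc)
            summary["parameters"].setdefault("caller", {})[label] = asdict(cc)
            tracks_norm[label] = peak_calling.normalize_to_wce(ip, wce)
            ps = peak_calling.call_peaks(ip, wce, cc)
            peak_sets[label] = ps
            write_peaks_bed(ps, outdir / f"{label}.peaks.bed")
            summary.setdefault("peak_counts", {})[label] = len(ps)

        # ---- genes and expression
        _stage("read gene annotation")
        if not Path(config.genes_path).exists():
            raise FileNotFoundError(
                f"stage 'gene annotation': missing {config.genes_path!r}")
        genes = read_gene_annotation(config.genes_path)
        if config.rpkm_path is not None:
            if not Path(config.rpkm_path).exists():
                raise FileNotFoundError(
                    f"stage 'expression': missing rpkm table "
                    f"{config.rpkm_path!r}")
            genes = attach_expression(genes, read_rpkm_table(config.rpkm_path))

        query = peak_sets[config.query_dataset]
        summary["classification"] = {}
        summary["expression"] = {}
        for ref_label in config.reference_datasets:
            _stage(f"partition {config.query_dataset} by {ref_label}")
            part = classification.overlap_partition(
                query, peak_sets[ref_label], pad_bp=config.pad_bp)
            key = f"{config.query_dataset}_by_{ref_label}"
            write_peaks_bed(part.positive_set, outdir / f"{key}.positive.bed")
            write_peaks_bed(part.negative_set, outdir / f"{key}.negative.bed")
            frac = len(part.positive_set) / len(query) if len(query) else 0.0
            summary["classification"][key] = {
                "n_positive": len(part.positive_set),
                "n_negative": len(part.negative_set),
                "positive_fraction": frac,
            }
            for name, subset in (("positive", part.positive_set),
                                 ("negative", part.negative_set)):
                if len(subset):
                    table = classification.category_fractions(subset, genes)
                    summary["classification"][key][f"{name}_categories"] = \
                        table.fractions

            # expression comparison
            if config.rpkm_path is not None and len(part.positive_set) \
                    and len(part.negative_set):
                _stage(f"expression: {key}")
                pos, neg = association.group_expression(part, genes)
                _write_vectors(outdir / f"{key}.expression.tsv",
                               {"positive": pos, "negative": neg})
                rs = st.rank_sum_one_sided(pos, neg, alternative="greater")
                pm = st.permutation_pvalue(pos, neg, statistic="median_diff",
                                           n_perm=config.n_perm,
                                           seed=config.seed,
                                           alternative="greater")
                summary["expression"][key] = {
                    "n_positive": len(pos),
                    "n_negative": len(neg),
                    "median_positive": float(np.median(pos)) if len(pos) else None,
                    "median_negative": float(np.median(neg)) if len(neg) else None,
                    "ranksum_p_one_sided": rs.p_value,
                    "permutation_p": pm.p_value,
                }

            # distance profiles to auxiliary datasets
            for dist_label in config.distance_datasets:
                _stage(f"distances: {key} -> {dist_label}")
                target = peak_sets[dist_label]
                for name, subset in (("positive", part.positive_set),
                                     ("negative", part.negative_set)):
                    if not len(subset):
                        continue
                    dists = [association.nearest_peak_distance(p, target)
                             for p in subset]
                    prof = association.distance_profile(
                        dists, bin_width=config.bin_width_bp,
                        source_label=f"{key}.{name}", target_label=dist_label)
                    _write_profile(
                        outdir / f"{key}.{name}.dist_{dist_label}.tsv", prof)
                    summary.setdefault("distance_bin0", {})[
                        f"{key}.{name}->{dist_label}"] = float(
                            prof.frequencies[0]) if len(prof.frequencies) else 0.0

            # exclusion re-analysis
            if config.exclusion_dataset and config.rpkm_path is not None:
                _stage(f"exclusion re-analysis: {config.exclusion_dataset}")
                excl = peak_sets[config.exclusion_dataset]
                res = {}
                for name, subset in (("positive", part.positive_set),
                                     ("negative", part.negative_set)):
                    over, clear = classification.exclusion_split(subset, excl)
                    res[f"{name}_clear_fraction"] = (
                        len(clear) / len(subset) if len(subset) else None)
                summary["classification"][key]["exclusion"] = res

        # ---- write summary
        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_summary_tsv(outdir / "summary.tsv", summary)
        log.info("summary written to %s", summary_path)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_vectors(path, vectors: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        fh.write("group\tvalue\n")
        for label, vals in vectors.items():
            for v in vals:
                fh.write(f"{label}\t{v}\n")


def _write_profile(path, prof) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start_bp\tcount\tfrequency\n")
        for k, (c, f) in enumerate(zip(prof.counts, prof.frequencies)):
            fh.write(f"{k * prof.bin_width_bp}\t{c}\t{f}\n")


def _flatten(prefix: str, obj, rows: list) -> None:
    if isinstance(obj, dict):
        for k, v in sorted(obj.items()):
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    else:
        rows.append((prefix, obj))


def _write_summary_tsv(path, summary: dict) -> None:
    rows: list = []
    _flatten("", summary, rows)
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")
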