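import numpy as np
import pytest

from cohescan import CallerConfig, Gene, GeneSet, Peak, PeakSet, ProbeTrack


def make_track(values, chromosome="chr2", spacing=250, start=0, label="Rad21"):
    """A probe track on a regular grid from a list of linear-scale values."""
    values = np.asarray(values, dtype=float)
    positions = start + np.arange(len(values)) * spacing
    return ProbeTrack(chromosome, positions, values, dataset_label=label)


def make_pair_from_log2(log2_values, chromosome="chr2", spacing=250, start=0,
                        label="Rad21", baseline=100.0):
    """An (ip, wce) pair whose normalized track equals ``log2_values``.

    Entries set to None become masked probes (IP channel zeroed).
    """
    vals = [0.0 if v is None else float(v) for v in log2_values]
    wce = make_track([baseline] * len(vals), chromosome, spacing, start, "WCE")
    ip_vals = baseline * np.exp2(np.asarray(vals))
    for i, v in enumerate(log2_values):
        if v is None:
            ip_vals[i] = 0.0
    ip = ProbeTrack(wce.chromosome, wce.positions.copy(), ip_vals,
                    dataset_label=label)
    return ip, wce


def peak(chromosome="chr2", start=0, end=1000, apex=None, mean=0.5,
         n_probes=4):
    return Peak(chromosome=chromosome, start=start, end=end,
                apex_position=start if apex is None else apex,
                mean_log2=mean, sum_log2=mean * n_probes, n_probes=n_probes)


def peak_set(intervals, chromosome="chr2", label="Rad21", mean=0.5):
    return PeakSet(label, [peak(chromosome, s, e, mean=mean)
                           for s, e in intervals])


@pytest.fixture
def simple_genes():
    return GeneSet([
        Gene("mrna1", "chr2", 100, 2000, "+", "II", rpkm=600.0),
        Gene("mrna2", "chr2", 5000, 7000, "-", "II", rpkm=10.0),
        Gene("trna1", "chr2", 3000, 3100, "+", "III", rpkm=None),
        Gene("mrna3", "chr3", 0, 1000, "+", "II", rpkm=50.0),
    ])
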