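"""Partition cohesin peaks into cohesive and non-cohesive sets.

Simulates a cohesin (Rad21) and a loader (Mis4) dataset in which a third
of the cohesin peaks are co-planted with a loader peak, calls peaks on
both, and splits the cohesin set by loader overlap — the operation that
defines cohesive (Mis4+/Rad21+) versus non-cohesive (Rad21+) sites.
"""

from cohescan import (
    call_peaks,
    default_config,
    landscape_config,
    overlap_partition,
    simulate_tracks,
)

config = landscape_config(n_query_peaks=150, n_reference_peaks=80,
                          cohesive_fraction=0.33, seed=5)
tracks, truth = simulate_tracks(config)

rad21 = call_peaks(*tracks["Rad21"], default_config("Rad21"))
mis4 = call_peaks(*tracks["Mis4"], default_config("Mis4"))
split = overlap_partition(rad21, mis4, pad_bp=0)

frac = len(split.positive_set) / len(rad21)
print(f"Rad21 peaks: {len(rad21)}, Mis4 peaks: {len(mis4)}")
print(f"cohesive (Mis4+/Rad21+): {len(split.positive_set)}")
print(f"non-cohesive (Rad21+):   {len(split.negative_set)}")
print(f"cohesive fraction: {frac:.2f} "
      f"(planted: {len(truth.cohesive_pairs) / 150:.2f})")
print("The recovered fraction tracks the planted co-localization rate; "
      "small deviations come from noise peaks entering the Rad21 set.")
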