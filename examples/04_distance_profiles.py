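"""Distance profiles from cohesin peaks to a maintenance-factor track.

Plants a Pds5-like dataset only at the cohesive cohesin sites, then
profiles the margin distance from each cohesin group to its nearest Pds5
peak in 5-kb bins: the cohesive group should pile up in bin 0.
"""

from cohescan import (
    PlantedPeak,
    call_peaks,
    default_config,
    distance_profile,
    landscape_config,
    nearest_peak_distance,
    overlap_partition,
    simulate_tracks,
)

config = landscape_config(n_query_peaks=120, n_reference_peaks=60,
                          cohesive_fraction=0.4, seed=21)
# plant Pds5 exactly at the cohesive (co-planted) sites
config.datasets["Pds5"] = [PlantedPeak(a.start, a.end, 1.0)
                           for a, _ in config._pairs]
tracks, truth = simulate_tracks(config)

rad21 = call_peaks(*tracks["Rad21"], default_config("Rad21"))
mis4 = call_peaks(*tracks["Mis4"], default_config("Mis4"))
pds5 = call_peaks(*tracks["Pds5"], default_config("Pds5"))
split = overlap_partition(rad21, mis4)

for name, group in (("cohesive", split.positive_set),
                    ("non-cohesive", split.negative_set)):
    dists = [nearest_peak_distance(p, pds5) for p in group]
    prof = distance_profile(dists, bin_width=5000, source_label=name,
                            target_label="Pds5")
    head = "  ".join(f"{f:.2f}" for f in prof.frequencies[:5])
    print(f"{name:>13} (n={prof.n_total:>3}): bin frequencies "
          f"[0,5k,10k,15k,20k) = {head}")
print("Frequencies are normalized to the group size. Bin 0 holds peaks "
      "overlapping or adjacent to a Pds5 peak; the cohesive group's bin-0 "
      "mass dominates because Pds5 was planted only there.")
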