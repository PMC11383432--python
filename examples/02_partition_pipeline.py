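"""Run the track-processing chain and compute the per-bin partition statistic.

Chain per strand: bin fragment midpoints (500 bp) -> CPM normalize -> uniform
blur (5 bins each side) -> subtract the identically processed input, clamping
negatives at zero -> Partition = (F - R)/(F + R) per bin.
"""

import numpy as np

from xscar import (
    SimConfig,
    bin_counts,
    blur_stranded,
    build_fork_map,
    compute_partition,
    cpm_normalize,
    simulate_origins,
    simulate_scar_experiment,
    subtract_input_clamp,
)

config = SimConfig(seed=42, p_lead=0.8)
origins = simulate_origins(config)
forks = build_fork_map(origins, config.contig_lengths)
parental, _, input_reads = simulate_scar_experiment(config, forks, origins)


def chain(reads):
    counts = bin_counts(reads, config.contig_lengths, bin_size=500)
    return blur_stranded(cpm_normalize(counts, reads.library_size), half_window=5)


corrected = subtract_input_clamp(chain(parental), chain(input_reads))
partition = compute_partition(corrected)

print(f"missing-bin fraction (no nascent signal): {partition.missing_fraction():.3f}")
center = int(origins.df.iloc[0]["center"])
contig = origins.df.iloc[0]["contig"]
bins = np.arange(center // 500 - 6, center // 500 + 7)
print(f"partition around origin {contig}:{center} (one value per 500 bp bin):")
with np.printoptions(precision=2, suppress=True):
    print(partition.data[contig][bins])
print("negative left of the center (leading strand = reverse), positive right of it")
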