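"""Aggregate the partition around replication origins: metaprofile and heatmap.

Origins are filtered at firing score > 20; the metaprofile is the mean
partition per offset from the origin center, and its right-flank plateau
(beyond the blur reach) recovers 2*p_lead - 1.
"""

import os

from xscar import (
    SimConfig,
    bin_counts,
    blur_stranded,
    build_fork_map,
    compute_partition,
    cpm_normalize,
    filter_origins,
    heatmap_matrix,
    metaprofile,
    simulate_origins,
    simulate_scar_experiment,
    subtract_input_clamp,
)
from xscar.plotting import plot_heatmap, plot_metaprofile

config = SimConfig(seed=42, p_lead=0.8)
p_lead = config.p_lead
origins = simulate_origins(config)
forks = build_fork_map(origins, config.contig_lengths)
parental, _, input_reads = simulate_scar_experiment(config, forks, origins)


def chain(reads):
    counts = bin_counts(reads, config.contig_lengths, bin_size=500)
    return blur_stranded(cpm_normalize(counts, reads.library_size), half_window=5)


partition = compute_partition(subtract_input_clamp(chain(parental), chain(input_reads)))

used = filter_origins(origins, min_score=20.0)
print(f"origins retained by score > 20 filter: {len(used)} of {len(origins)}")

profile = metaprofile(partition, used, flank=5000)
print("offset (bp)  mean partition  n origins")
for off, mean, n in zip(profile.offsets, profile.mean, profile.n):
    print(f"{off:10.0f}  {mean:14.3f}  {n:9d}")

plateau = profile.plateau(2500, 5000)
print(f"right-flank plateau: {plateau:.3f} (expected 2*p_lead - 1 = {2 * p_lead - 1:.2f})")

matrix = heatmap_matrix(partition, used, flank=5000)
print(f"heatmap: {matrix.values.shape[0]} origins x {matrix.values.shape[1]} offset bins")

out_dir = "xscar_example_out"
os.makedirs(out_dir, exist_ok=True)
plot_metaprofile(profile).figure.savefig(os.path.join(out_dir, "metaprofile.png"), dpi=150)
plot_heatmap(matrix).figure.savefig(os.path.join(out_dir, "heatmap.png"), dpi=150)
print(f"figures written to {out_dir}/")
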