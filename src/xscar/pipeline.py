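"""Orchestration: simulate -> tracks -> partition -> aggregate, as files.

Every stage writes plain-text outputs (BED, bedGraph, TSV, YAML) into the
configured output directory, and every stage can be re-run from the files
the previous stage wrote. Runs are deterministic: fixed inputs and
configuration produce byte-identical outputs (floats are written with
round-trip precision and the run summary carries no timestamps).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping

import yaml

from . import origins as org
from . import partition as part
from . import tracks as trk
from .config import RunConfig
from .readio import StrandedReadSet, read_alignments
from .simulate import SimConfig, build_fork_map, simulate_origins, simulate_scar_experiment, write_reads

logger = logging.getLogger(__name__)

CHIP_SAMPLES = ("parental", "new")


def write_genome_tsv(contig_lengths: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for contig, length in contig_lengths.items():
            fh.write(f"{contig}\t{length}\n")


def read_genome_tsv(path: str | os.PathLike) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected contig<TAB>length")
            out[fields[0]] = int(fields[1])
    if not out:
        raise ValueError(f"{path}: empty genome declaration")
    return out


def write_origins_bedgraph(origin_set: org.OriginSet, path: str | os.PathLike) -> None:
    """Write origins as (contig, center, center+1, score) bedGraph-like text."""
    with open(path, "w") as fh:
        for row in origin_set.df.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.center}\t{row.center + 1}\t{row.score:.17g}\n")


def run_simulate(config: SimConfig, out_dir: str | os.PathLike) -> dict[str, str]:
    """Simulate one experiment and write reads, origins, genome, and manifest.

    Deterministic per seed: the same config writes byte-identical files.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    origin_set = simulate_origins(config)
    forks = build_fork_map(origin_set, config.contig_lengths)
    parental, new, input_reads = simulate_scar_experiment(config, forks, origin_set)
    paths = {
        "parental": os.path.join(out_dir, "parental.bed"),
        "new": os.path.join(out_dir, "new.bed"),
        "input": os.path.join(out_dir, "input.bed"),
        "origins": os.path.join(out_dir, "origins.bedgraph"),
        "genome": os.path.join(out_dir, "genome.tsv"),
        "manifest": os.path.join(out_dir, "manifest.yaml"),
    }
    write_reads(parental, paths["parental"], "bed")
    write_reads(new, paths["new"], "bed")
    write_reads(input_reads, paths["input"], "bed")
    write_origins_bedgraph(origin_set, paths["origins"])
    write_genome_tsv(config.contig_lengths, paths["genome"])
    manifest = {
        "sim_config": config.to_dict(),
        "files": {k: os.path.basename(v) for k, v in paths.items() if k != "manifest"},
        "library_sizes": {
            "parental": parental.library_size,
            "new": new.library_size,
            "input": input_reads.library_size,
        },
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("simulated experiment written to %s", out_dir)
    return paths


def sample_cpm_track(
    reads: StrandedReadSet,
    contig_lengths: Mapping[str, int],
    bin_size: int,
    half_window: int,
    blur: bool = True,
) -> trk.StrandedBinnedTrack:
    """bin -> CPM -> blur chain for one sample."""
    counts = trk.bin_counts(reads, contig_lengths, bin_size)
    cpm = trk.cpm_normalize(counts, reads.library_size)
    return trk.blur_stranded(cpm, half_window) if blur else cpm


@dataclass
class SampleResult:
    """Per-ChIP-sample products of the partition chain."""

    name: str
    corrected: trk.StrandedBinnedTrack
    partition: part.PartitionTrack
    metaprofile: org.MetaProfile | None = None
    heatmap: org.HeatmapMatrix | None = None
    density: org.DensityProfile | None = None


def _load_reads(cfg: RunConfig, contig_lengths: Mapping[str, int]) -> dict[str, StrandedReadSet]:
    reads: dict[str, StrandedReadSet] = {}
    for name in (*CHIP_SAMPLES, "input"):
        path = getattr(cfg, name)
        if path is not None:
            reads[name] = read_alignments(
                path, format=cfg.format, pairing=cfg.pairing, contig_lengths=contig_lengths
            )
    if not any(n in reads for n in CHIP_SAMPLES):
        raise ValueError("no ChIP sample declared: set 'parental' and/or 'new'")
    return reads


def run_partition(cfg: RunConfig) -> dict[str, SampleResult]:
    """Full analysis for every declared ChIP sample.

    For each sample: bin/CPM/blur, subtract the identically processed input
    (clamping at zero), compute the partition, apply the chemistry flip if
    the library used mirrored-UMI adapters, then aggregate over the
    score-filtered origins into metaprofile/heatmap/density tables. Writes
    bedGraphs, TSVs and a deterministic run summary under ``cfg.out_dir``.
    """
    cfg.resolve()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if cfg.genome is None:
        raise ValueError("config field 'genome' (contig-length TSV) is required")
    contig_lengths = read_genome_tsv(cfg.genome)
    os.makedirs(cfg.out_dir, exist_ok=True)
    reads = _load_reads(cfg, contig_lengths)

    cpm_tracks = {
        name: sample_cpm_track(
            rs, contig_lengths, cfg.bin_size, cfg.half_window,
            blur=(cfg.blur_input if name == "input" else True),
        )
        for name, rs in reads.items()
    }

    origin_set = None
    if cfg.origins is not None:
        origin_set = org.filter_origins(org.load_origins(cfg.origins), cfg.min_origin_score)
        origin_set.check_bounds(contig_lengths)

    summary_lines = ["# run summary", "## effective parameters"]
    path_fields = {"parental", "new", "input", "origins", "genome"}
    for key, value in sorted(cfg.to_dict().items()):
        if key == "out_dir":
            continue  # keep the summary independent of where it is written
        if key in path_fields and value is not None:
            value = os.path.basename(str(value))
        summary_lines.append(f"{key}: {value}")
    summary_lines.append("## library sizes")
    for name in sorted(reads):
        summary_lines.append(f"{name}: {reads[name].library_size}")

    results: dict[str, SampleResult] = {}
    for name in CHIP_SAMPLES:
        if name not in reads:
            continue
        signal = cpm_tracks[name]
        if "input" in cpm_tracks:
            corrected = trk.subtract_input_clamp(signal, cpm_tracks["input"])
        else:
            corrected = signal
        p = part.compute_partition(corrected)
        if cfg.chemistry == "mirrored-umi":
            p = part.flip_orientation(p)
        res = SampleResult(name, corrected, p)

        trk.write_bedgraph(corrected.forward, os.path.join(cfg.out_dir, f"{name}_fwd_cpm.bedgraph"))
        trk.write_bedgraph(corrected.reverse, os.path.join(cfg.out_dir, f"{name}_rev_cpm.bedgraph"))
        part.write_partition_bedgraph(p, os.path.join(cfg.out_dir, f"{name}_partition.bedgraph"))
        trk.write_bedgraph(
            part.coverage_track(corrected), os.path.join(cfg.out_dir, f"{name}_coverage.bedgraph")
        )
        summary_lines.append(f"## sample {name}")
        summary_lines.append(f"missing_bin_fraction: {p.missing_fraction():.17g}")

        if origin_set is not None and len(origin_set):
            res.heatmap = org.heatmap_matrix(p, origin_set, cfg.flank)
            res.metaprofile = org.metaprofile(p, origin_set, cfg.flank, orient=cfg.orient)
            res.heatmap.to_tsv(os.path.join(cfg.out_dir, f"{name}_heatmap.tsv"))
            res.metaprofile.to_tsv(os.path.join(cfg.out_dir, f"{name}_metaprofile.tsv"))
            summary_lines.append(f"origins_used: {res.metaprofile.n_origins_used}")
            summary_lines.append(f"origins_dropped: {res.metaprofile.n_origins_dropped}")
            if "input" in reads:
                res.density = org.density_profile(
                    reads[name], reads["input"], origin_set,
                    flank=cfg.flank, bin_size=cfg.bin_size,
                    input_stratification=cfg.density_input_stratification,
                )
                res.density.to_tsv(os.path.join(cfg.out_dir, f"{name}_density.tsv"))
        results[name] = res

    with open(os.path.join(cfg.out_dir, "run_summary.txt"), "w") as fh:
        fh.write("\n".join(summary_lines) + "\n")
    return results


def run_tracks(cfg: RunConfig) -> dict[str, trk.StrandedBinnedTrack]:
    """Stage: write blurred CPM bedGraphs (pre-subtraction) for every sample."""
    cfg.resolve()
    if cfg.genome is None:
        raise ValueError("config field 'genome' (contig-length TSV) is required")
    contig_lengths = read_genome_tsv(cfg.genome)
    os.makedirs(cfg.out_dir, exist_ok=True)
    reads = _load_reads(cfg, contig_lengths)
    out: dict[str, trk.StrandedBinnedTrack] = {}
    for name, rs in reads.items():
        track = sample_cpm_track(
            rs, contig_lengths, cfg.bin_size, cfg.half_window,
            blur=(cfg.blur_input if name == "input" else True),
        )
        trk.write_bedgraph(track.forward, os.path.join(cfg.out_dir, f"{name}_fwd_blurcpm.bedgraph"))
        trk.write_bedgraph(track.reverse, os.path.join(cfg.out_dir, f"{name}_rev_blurcpm.bedgraph"))
        out[name] = track
    return out


def run_aggregate(cfg: RunConfig) -> dict[str, SampleResult]:
    """Stage: rebuild aggregates from previously written partition bedGraphs.

    Re-running this stage on the files ``run_partition`` wrote reproduces
    its metaprofile/heatmap/density tables exactly.
    """
    cfg.resolve()
    if cfg.genome is None or cfg.origins is None:
        raise ValueError("aggregate stage requires 'genome' and 'origins' config fields")
    contig_lengths = read_genome_tsv(cfg.genome)
    origin_set = org.filter_origins(org.load_origins(cfg.origins), cfg.min_origin_score)
    origin_set.check_bounds(contig_lengths)
    results: dict[str, SampleResult] = {}
    reads: dict[str, StrandedReadSet] | None = None
    for name in CHIP_SAMPLES:
        path = os.path.join(cfg.out_dir, f"{name}_partition.bedgraph")
        if not os.path.exists(path):
            continue
        p = part.read_partition_bedgraph(
            path, contig_lengths, cfg.bin_size, flipped=(cfg.chemistry == "mirrored-umi")
        )
        res = SampleResult(name, corrected=None, partition=p)  # type: ignore[arg-type]
        res.heatmap = org.heatmap_matrix(p, origin_set, cfg.flank)
        res.metaprofile = org.metaprofile(p, origin_set, cfg.flank, orient=cfg.orient)
        res.heatmap.to_tsv(os.path.join(cfg.out_dir, f"{name}_heatmap.tsv"))
        res.metaprofile.to_tsv(os.path.join(cfg.out_dir, f"{name}_metaprofile.tsv"))
        if getattr(cfg, name) is not None and cfg.input is not None:
            if reads is None:
                reads = _load_reads(cfg, contig_lengths)
            res.density = org.density_profile(
                reads[name], reads["input"], origin_set,
                flank=cfg.flank, bin_size=cfg.bin_size,
                input_stratification=cfg.density_input_stratification,
            )
            res.density.to_tsv(os.path.join(cfg.out_dir, f"{name}_density.tsv"))
        results[name] = res
    if not results:
        raise ValueError(f"no partition bedGraphs found under {cfg.out_dir}")
    return results


def run_all(sim_config: SimConfig, cfg: RunConfig | None = None) -> dict[str, SampleResult]:
    """simulate -> partition/aggregate in one call.

    ``cfg`` supplies analysis parameters; its sample/genome/origin paths are
    filled in from the simulation outputs. Everything lands in
    ``cfg.out_dir`` (simulation files under ``<out_dir>/sim``).
    """
    cfg = cfg or RunConfig()
    sim_dir = os.path.join(cfg.out_dir, "sim")
    paths = run_simulate(sim_config, sim_dir)
    cfg.parental = paths["parental"]
    cfg.new = paths["new"]
    cfg.input = paths["input"]
    cfg.origins = paths["origins"]
    cfg.genome = paths["genome"]
    cfg.format = "bed"
    cfg.seed = sim_config.seed
    return run_partition(cfg)
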