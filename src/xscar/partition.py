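"""The per-bin partition statistic and its orientation correction.

Partition = (F - R) / (F + R), where F and R are the normalized,
input-corrected forward- and reverse-strand signals in a bin. It measures
which nascent strand inherited the immunoprecipitated histones: values > 0
mean forward-strand (and, right of an origin, leading-strand) enrichment,
values < 0 reverse-strand enrichment. Bins with F + R = 0 carry no
information and are missing (NaN), not zero — zero would fake perfect
symmetry and bias downstream averages.

Some library chemistries (xGen UDI-UMI adapters) sequence the complementary
strand, which mirrors the observed ratio into (R - F)/(R + F);
:func:`flip_orientation` restores the standard sign by negation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .tracks import BinnedTrack, StrandedBinnedTrack, zero_track, _FLOAT_FMT


@dataclass
class PartitionTrack:
    """Per-contig, per-bin partition values in [-1, 1]; NaN marks missing bins."""

    data: dict[str, np.ndarray]
    bin_size: int
    contig_lengths: dict[str, int]
    flipped: bool = False

    def __post_init__(self) -> None:
        for contig in self.data:
            arr = np.asarray(self.data[contig], dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
                raise ValueError(f"{contig}: partition values outside [-1, 1]")
            self.data[contig] = arr

    def missing_fraction(self) -> float:
        total = sum(arr.size for arr in self.data.values())
        if total == 0:
            return 0.0
        nan = sum(int(np.isnan(arr).sum()) for arr in self.data.values())
        return nan / total


def compute_partition(corrected: StrandedBinnedTrack) -> PartitionTrack:
    """Compute (F - R)/(F + R) per bin from an input-corrected stranded track.

    Requires all bin values to be non-negative (the contract of
    subtract-and-clamp); raises otherwise. Bins where F + R = 0 become NaN.
    """
    data: dict[str, np.ndarray] = {}
    for contig in corrected.contig_lengths:
        f = corrected.forward.data[contig]
        r = corrected.reverse.data[contig]
        if (f < 0).any() or (r < 0).any():
            raise ValueError(
                f"{contig}: negative strand signal; partition requires "
                "input-corrected (clamped, non-negative) tracks"
            )
        denom = f + r
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (f - r) / denom
        p[denom == 0] = np.nan
        data[contig] = p
    return PartitionTrack(
        data, corrected.bin_size, dict(corrected.contig_lengths), flipped=False
    )


def flip_orientation(p: PartitionTrack) -> PartitionTrack:
    """Negate every non-missing partition value (mirrored-UMI correction).

    Missing bins stay missing; applying the flip twice is the identity.
    """
    data = {c: -arr for c, arr in p.data.items()}
    return PartitionTrack(data, p.bin_size, dict(p.contig_lengths), flipped=not p.flipped)


def coverage_track(corrected: StrandedBinnedTrack) -> BinnedTrack:
    """F + R per bin — the companion coverage used to gate partition values."""
    out = zero_track(corrected.contig_lengths, corrected.bin_size)
    for contig in out.data:
        out.data[contig] = (
            corrected.forward.data[contig] + corrected.reverse.data[contig]
        )
    return out


def write_partition_bedgraph(p: PartitionTrack, path: str | os.PathLike) -> None:
    """Write partition values as bedGraph, omitting missing bins."""
    with open(path, "w") as fh:
        for contig, length in p.contig_lengths.items():
            values = p.data[contig]
            b = p.bin_size
            for i, v in enumerate(values):
                if np.isnan(v):
                    continue
                end = min((i + 1) * b, length)
                fh.write(f"{contig}\t{i * b}\t{end}\t{_FLOAT_FMT % v}\n")


def read_partition_bedgraph(
    path: str | os.PathLike,
    contig_lengths: dict[str, int],
    bin_size: int,
    flipped: bool = False,
) -> PartitionTrack:
    """Load a partition bedGraph written by :func:`write_partition_bedgraph`.

    Bins absent from the file are missing (NaN).
    """
    from .tracks import read_bedgraph

    track = read_bedgraph(path, contig_lengths, bin_size, missing=np.nan)
    return PartitionTrack(track.data, bin_size, dict(contig_lengths), flipped=flipped)
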