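"""Binned stranded signal tracks: counting, CPM scaling, smoothing, input correction.

The processing chain that turns stranded fragments into the F and R
quantities of the partition statistic is, per strand:

    bin midpoints -> CPM normalize -> uniform blur -> subtract input, clamp at 0

The ChIP sample and its clicked-EdU input are taken through the identical
bin/CPM/blur chain before subtraction so the two are on the same scale.
CPM uses the sample's total fragment count over both strands — per-strand
normalization would erase the strand asymmetry the partition measures.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .readio import FORWARD, StrandedReadSet

_FLOAT_FMT = "%.17g"


@dataclass
class BinnedTrack:
    """Per-contig, per-bin real-valued signal on a fixed bin grid.

    The last bin of a contig may cover a shorter genomic span; it is kept
    with the same divisor as full bins.
    """

    data: dict[str, np.ndarray]
    bin_size: int
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for contig, length in self.contig_lengths.items():
            expected = n_bins(length, self.bin_size)
            arr = np.asarray(self.data[contig], dtype=float)
            if arr.shape != (expected,):
                raise ValueError(
                    f"{contig}: expected {expected} bins, got {arr.shape}"
                )
            self.data[contig] = arr

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.contig_lengths == other.contig_lengths
        )

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            {c: v.copy() for c, v in self.data.items()},
            self.bin_size,
            dict(self.contig_lengths),
        )


@dataclass
class StrandedBinnedTrack:
    """Forward and reverse :class:`BinnedTrack` on one shared bin grid."""

    forward: BinnedTrack
    reverse: BinnedTrack
    library_size: int | None = None

    def __post_init__(self) -> None:
        if not self.forward.same_grid(self.reverse):
            raise ValueError("forward and reverse tracks are on different bin grids")

    @property
    def bin_size(self) -> int:
        return self.forward.bin_size

    @property
    def contig_lengths(self) -> dict[str, int]:
        return self.forward.contig_lengths

    def same_grid(self, other: "StrandedBinnedTrack") -> bool:
        return self.forward.same_grid(other.forward)

    def total(self) -> float:
        return self.forward.total() + self.reverse.total()


def n_bins(contig_length: int, bin_size: int) -> int:
    return math.ceil(contig_length / bin_size)


def zero_track(contig_lengths: Mapping[str, int], bin_size: int) -> BinnedTrack:
    data = {c: np.zeros(n_bins(l, bin_size)) for c, l in contig_lengths.items()}
    return BinnedTrack(data, bin_size, dict(contig_lengths))


def bin_counts(
    reads: StrandedReadSet,
    contig_lengths: Mapping[str, int],
    bin_size: int,
) -> StrandedBinnedTrack:
    """Count fragment midpoints into fixed-width bins, split by strand.

    A fragment whose midpoint is at position p increments bin floor(p /
    bin_size) of its strand's track. The total over both strands equals the
    library size exactly.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    fwd = zero_track(contig_lengths, bin_size)
    rev = zero_track(contig_lengths, bin_size)
    df = reads.df
    if len(df):
        for contig, sub in df.groupby("contig", sort=False):
            if contig not in contig_lengths:
                raise ValueError(f"fragment on undeclared contig {contig!r}")
            length = contig_lengths[contig]
            if (sub["start"].to_numpy() < 0).any() or (sub["end"].to_numpy() > length).any():
                raise ValueError(f"fragment beyond bounds of contig {contig!r}")
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            bins = mids // bin_size
            is_fwd = (sub["strand"] == FORWARD).to_numpy()
            nb = n_bins(length, bin_size)
            fwd.data[contig] += np.bincount(bins[is_fwd], minlength=nb).astype(float)
            rev.data[contig] += np.bincount(bins[~is_fwd], minlength=nb).astype(float)
    return StrandedBinnedTrack(fwd, rev, library_size=reads.library_size)


def cpm_normalize(track: StrandedBinnedTrack, library_size: int) -> StrandedBinnedTrack:
    """Scale every bin by 1e6 / library_size (counts per million fragments).

    ``library_size`` is the sample's total fragment count across both
    strands, not a per-strand total.
    """
    if library_size <= 0:
        raise ValueError("library_size must be a positive integer")
    scale = 1e6 / library_size
    out = StrandedBinnedTrack(track.forward.copy(), track.reverse.copy(), track.library_size)
    for tr in (out.forward, out.reverse):
        for contig in tr.data:
            tr.data[contig] *= scale
    return out


def uniform_blur(track: BinnedTrack, half_window: int) -> BinnedTrack:
    """Moving-average smoothing over ``half_window`` bins on each side.

    Interior bin i becomes the mean of bins [i-h, i+h]. Within h bins of a
    contig edge the mean is taken over the bins that exist (truncated
    window), so edge values stay within the [min, max] range of the raw
    track. ``half_window = 0`` is the identity.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    out = track.copy()
    if half_window == 0:
        return out
    h = half_window
    for contig, values in track.data.items():
        n = len(values)
        if n == 0:
            continue
        cs = np.concatenate(([0.0], np.cumsum(values)))
        idx = np.arange(n)
        lo = np.maximum(idx - h, 0)
        hi = np.minimum(idx + h, n - 1)
        out.data[contig] = (cs[hi + 1] - cs[lo]) / (hi - lo + 1)
    return out


def blur_stranded(track: StrandedBinnedTrack, half_window: int) -> StrandedBinnedTrack:
    """Apply :func:`uniform_blur` to both strands of a stranded track."""
    return StrandedBinnedTrack(
        uniform_blur(track.forward, half_window),
        uniform_blur(track.reverse, half_window),
        track.library_size,
    )


def subtract_input_clamp(
    signal: StrandedBinnedTrack, input_track: StrandedBinnedTrack
) -> StrandedBinnedTrack:
    """Per strand, per bin: max(signal - input, 0).

    Both tracks must be on the same bin grid and should have been taken
    through the identical CPM/blur chain. Negative differences are set to
    zero, matching the convention that input-corrected coverage cannot be
    negative.
    """
    if not signal.same_grid(input_track):
        raise ValueError("signal and input tracks are on different bin grids")
    fwd = signal.forward.copy()
    rev = signal.reverse.copy()
    for contig in fwd.data:
        fwd.data[contig] = np.maximum(fwd.data[contig] - input_track.forward.data[contig], 0.0)
        rev.data[contig] = np.maximum(rev.data[contig] - input_track.reverse.data[contig], 0.0)
    return StrandedBinnedTrack(fwd, rev, signal.library_size)


def write_bedgraph(track: BinnedTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph (contig, start, end, value), 0-based half-open."""
    with open(path, "w") as fh:
        for contig, length in track.contig_lengths.items():
            values = track.data[contig]
            b = track.bin_size
            for i, v in enumerate(values):
                end = min((i + 1) * b, length)
                fh.write(f"{contig}\t{i * b}\t{end}\t{_FLOAT_FMT % v}\n")


def read_bedgraph(
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int],
    bin_size: int,
    missing: float = 0.0,
) -> BinnedTrack:
    """Load a bin-aligned bedGraph back into a :class:`BinnedTrack`.

    Intervals must start on bin boundaries; absent bins take ``missing``.
    """
    track = zero_track(contig_lengths, bin_size)
    for arr in track.data.values():
        arr.fill(missing)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            contig, start = fields[0], int(fields[1])
            if contig not in contig_lengths:
                raise ValueError(f"{path}: line {lineno}: unknown contig {contig!r}")
            if start % bin_size:
                raise ValueError(f"{path}: line {lineno}: interval not bin-aligned")
            track.data[contig][start // bin_size] = float(fields[3])
    return track
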