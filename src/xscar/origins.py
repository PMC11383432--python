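"""Replication origins and origin-centered aggregation of partition signal.

Origins are replication initiation centers annotated with a firing-efficiency
score; low-firing origins (score <= 20 by the standard filter) are removed
before aggregation because forks around them have poorly defined
directionality. Around the retained origins this module builds:

* a metaprofile — the mean partition as a function of offset from the origin
  center (the sigmoid of the average-partitioning figures);
* a heatmap matrix — one row of per-bin partition values per origin;
* leading/lagging/unstranded density profiles — ChIP CPM over input CPM in
  bins around the centers, the no-net-loss control of the density analysis.

Strand-orientation convention, shared with the simulator: right of an origin
the leading strand maps to the forward reference strand, left of it to the
reverse strand; a position equidistant from two origins belongs to the
leftmost, and a position exactly at a center counts as right of it.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .partition import PartitionTrack
from .readio import FORWARD, StrandedReadSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 20.0
DEFAULT_FLANK = 2500


@dataclass
class OriginSet:
    """Replication initiation centers with firing-efficiency scores.

    Backed by a DataFrame with columns (contig, center, score);
    (contig, center) pairs are unique.
    """

    df: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        df = self.df.loc[:, ["contig", "center", "score"]].reset_index(drop=True)
        df["contig"] = df["contig"].astype(str)
        df["center"] = df["center"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        if df.duplicated(subset=["contig", "center"]).any():
            dup = df[df.duplicated(subset=["contig", "center"])].iloc[0]
            raise ValueError(
                f"duplicate origin center {dup['contig']}:{dup['center']}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def centers(self, contig: str) -> np.ndarray:
        """Sorted centers on one contig."""
        sub = self.df[self.df["contig"] == contig]["center"].to_numpy()
        return np.sort(sub)

    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.df["contig"]))

    def check_bounds(self, contig_lengths: Mapping[str, int]) -> None:
        for _, row in self.df.iterrows():
            if row["contig"] not in contig_lengths:
                raise ValueError(f"origin on unknown contig {row['contig']!r}")
            if not (0 <= row["center"] < contig_lengths[row["contig"]]):
                raise ValueError(
                    f"origin center {row['contig']}:{row['center']} outside contig"
                )


def load_origins(path: str | os.PathLike, source: str | None = None) -> OriginSet:
    """Load origins from bedGraph-like text (contig, start, end, score) or BED.

    The initiation center is floor((start + end) / 2); scores are preserved
    as given. 4-column files are read as (contig, start, end, score);
    files with >= 5 columns as BED with the score in column 5.
    """
    contigs: list[str] = []
    centers: list[int] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 4 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4] if len(fields) >= 5 else fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed record") from exc
            if not (0 <= start <= end):
                raise ValueError(f"{path}: line {lineno}: invalid interval")
            contigs.append(fields[0])
            centers.append((start + end) // 2)
            scores.append(score)
    df = pd.DataFrame({"contig": contigs, "center": centers, "score": scores})
    return OriginSet(df, source=source or str(path))


def filter_origins(origins: OriginSet, min_score: float = DEFAULT_MIN_SCORE) -> OriginSet:
    """Retain origins with firing score strictly greater than ``min_score``."""
    kept = origins.df[origins.df["score"] > min_score].reset_index(drop=True)
    return OriginSet(kept, source=origins.source)


def nearest_center_indices(centers: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Index of the nearest center for each position; equidistant ties go left.

    ``centers`` must be sorted ascending.
    """
    centers = np.asarray(centers)
    positions = np.asarray(positions)
    if centers.size == 0:
        raise ValueError("no centers to assign positions to")
    i = np.searchsorted(centers, positions)
    left = np.clip(i - 1, 0, centers.size - 1)
    right = np.clip(i, 0, centers.size - 1)
    d_left = np.abs(positions - centers[left])
    d_right = np.abs(centers[right] - positions)
    take_left = (i > 0) & ((i == centers.size) | (d_left <= d_right))
    return np.where(take_left, left, right)


def is_leading(offsets: np.ndarray, strands: np.ndarray) -> np.ndarray:
    """Label reads leading/lagging from signed origin offset and mapping strand.

    Right of the origin (offset >= 0) the leading nascent strand maps to the
    forward reference strand; left of it, to the reverse strand. Returns a
    boolean array, True = leading.
    """
    right = np.asarray(offsets) >= 0
    fwd = np.asarray(strands) == FORWARD
    return right == fwd


# ---------------------------------------------------------------------------
# origin-centered aggregates


@dataclass
class HeatmapMatrix:
    """Per-origin partition rows over a symmetric window of offsets.

    values[i, j] is the partition of origin i at offset offsets[j] (bin
    center minus origin center, bp); NaN marks missing bins.
    """

    origin_ids: list[str]
    offsets: np.ndarray
    values: np.ndarray
    scores: np.ndarray
    n_dropped: int = 0

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            cols = "\t".join("%g" % o for o in self.offsets)
            fh.write(f"origin\tscore\t{cols}\n")
            for oid, score, row in zip(self.origin_ids, self.scores, self.values):
                vals = "\t".join("nan" if np.isnan(v) else "%.17g" % v for v in row)
                fh.write(f"{oid}\t{score:.17g}\t{vals}\n")


@dataclass
class MetaProfile:
    """Mean partition per offset from the origin center, with support counts."""

    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    n_origins_used: int = 0
    n_origins_dropped: int = 0

    def plateau(self, lo: float, hi: float) -> float:
        """Mean profile value over offsets in [lo, hi) — a plateau estimate."""
        mask = (self.offsets >= lo) & (self.offsets < hi)
        if not mask.any():
            raise ValueError(f"no offsets in [{lo}, {hi})")
        return float(np.nanmean(self.mean[mask]))

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tmean_partition\tn_origins\n")
            for o, m, k in zip(self.offsets, self.mean, self.n):
                mtxt = "nan" if np.isnan(m) else "%.17g" % m
                fh.write(f"{o:g}\t{mtxt}\t{k:d}\n")


def window_offsets(flank: int, bin_size: int) -> np.ndarray:
    """Canonical bin-center offsets for a symmetric window of ±flank."""
    ncols = 2 * flank // bin_size
    return -flank + (np.arange(ncols) + 0.5) * bin_size


def heatmap_matrix(
    p: PartitionTrack, origins: OriginSet, flank: int = DEFAULT_FLANK
) -> HeatmapMatrix:
    """One row of per-bin partition values per usable origin.

    The window is [center - flank, center + flank); origins whose window
    exceeds contig bounds are dropped and counted. ``flank`` must be a
    positive multiple of the partition bin size.
    """
    bin_size = p.bin_size
    if flank <= 0 or flank % bin_size:
        raise ValueError(f"flank must be a positive multiple of bin_size {bin_size}")
    ncols = 2 * flank // bin_size
    offsets = window_offsets(flank, bin_size)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    scores: list[float] = []
    dropped = 0
    df = origins.df.sort_values(["contig", "center"], kind="mergesort")
    for _, row in df.iterrows():
        contig, center = row["contig"], int(row["center"])
        if contig not in p.data:
            raise ValueError(f"origin on contig {contig!r} absent from partition track")
        length = p.contig_lengths[contig]
        if center - flank < 0 or center + flank > length:
            dropped += 1
            logger.info("dropping origin %s:%d: window exceeds contig bounds", contig, center)
            continue
        b0 = (center - flank) // bin_size
        rows.append(p.data[contig][b0 : b0 + ncols])
        ids.append(f"{contig}:{center}")
        scores.append(float(row["score"]))
    if not rows:
        raise ValueError("no usable origins after bounds filtering")
    return HeatmapMatrix(
        ids, offsets, np.vstack(rows), np.asarray(scores), n_dropped=dropped
    )


def metaprofile(
    p: PartitionTrack,
    origins: OriginSet,
    flank: int = DEFAULT_FLANK,
    orient: str = "signed",
) -> MetaProfile:
    """Mean partition per offset across origins (column means of the heatmap).

    Missing bins are ignored per offset (the divisor is the count of
    non-missing values). ``orient='signed'`` keeps the raw signed profile
    (the sigmoid); ``orient='leading'`` negates left-flank values so both
    flanks report the leading-strand partition as a single plateau.
    """
    if orient not in ("signed", "leading"):
        raise ValueError(f"orient must be 'signed' or 'leading', got {orient!r}")
    m = heatmap_matrix(p, origins, flank)
    values = m.values
    if orient == "leading":
        values = values.copy()
        values[:, m.offsets < 0] *= -1.0
    n = (~np.isnan(values)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_sum = np.nansum(values, axis=0)
        mean = np.where(n > 0, col_sum / np.maximum(n, 1), np.nan)
    return MetaProfile(
        m.offsets,
        mean,
        n.astype(np.int64),
        n_origins_used=len(m.origin_ids),
        n_origins_dropped=m.n_dropped,
    )


@dataclass
class DensityProfile:
    """ChIP/input CPM ratio per offset bin, stratified by nascent strand.

    ``leading``/``lagging`` divide strand-labeled ChIP reads by the input
    stratum chosen at construction; ``unstranded`` divides totals by totals.
    NaN marks bins with zero input in the relevant denominator.
    """

    offsets: np.ndarray
    leading: np.ndarray
    lagging: np.ndarray
    unstranded: np.ndarray

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tleading\tlagging\tunstranded\n")
            for o, le, la, un in zip(self.offsets, self.leading, self.lagging, self.unstranded):
                row = "\t".join("nan" if np.isnan(v) else "%.17g" % v for v in (le, la, un))
                fh.write(f"{o:g}\t{row}\n")


def _window_strand_counts(
    reads: StrandedReadSet,
    origins: OriginSet,
    flank: int,
    bin_size: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(leading, lagging, total) counts per offset bin, pooled over origins."""
    nb = 2 * flank // bin_size
    lead = np.zeros(nb)
    lag = np.zeros(nb)
    df = reads.df
    for contig, sub in df.groupby("contig", sort=False):
        centers = origins.centers(contig)
        if centers.size == 0:
            continue
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        idx = nearest_center_indices(centers, mids)
        off = mids - centers[idx]
        keep = (off >= -flank) & (off < flank)
        if not keep.any():
            continue
        off = off[keep]
        strands = sub["strand"].to_numpy()[keep]
        bins = (off + flank) // bin_size
        leading = is_leading(off, strands)
        lead += np.bincount(bins[leading], minlength=nb)
        lag += np.bincount(bins[~leading], minlength=nb)
    return lead, lag, lead + lag


def density_profile(
    chip: StrandedReadSet,
    input_reads: StrandedReadSet,
    origins: OriginSet,
    flank: int = DEFAULT_FLANK,
    bin_size: int = 500,
    input_stratification: str = "matching",
) -> DensityProfile:
    """ChIP over input read density around origin centers, by nascent strand.

    Reads are restricted to [center - flank, center + flank) windows of the
    (already filtered) origins, labeled leading/lagging from their strand
    and side of the origin, CPM-normalized by each library's total size, and
    ratioed per offset bin. With ``input_stratification='matching'`` the
    stranded strata divide by the input reads carrying the same nascent-
    strand label; with ``'total'`` they divide by the total input.
    """
    if input_stratification not in ("matching", "total"):
        raise ValueError(
            f"input_stratification must be 'matching' or 'total', got {input_stratification!r}"
        )
    if len(origins) == 0:
        raise ValueError("empty origin set")
    if chip.library_size == 0 or input_reads.library_size == 0:
        raise ValueError("both ChIP and input read sets must be non-empty")
    if flank <= 0 or flank % bin_size:
        raise ValueError(f"flank must be a positive multiple of bin_size {bin_size}")
    c_lead, c_lag, c_tot = _window_strand_counts(chip, origins, flank, bin_size)
    i_lead, i_lag, i_tot = _window_strand_counts(input_reads, origins, flank, bin_size)
    if i_tot.sum() == 0:
        raise ValueError("no input reads within origin windows")
    c_scale = 1e6 / chip.library_size
    i_scale = 1e6 / input_reads.library_size
    if input_stratification == "matching":
        den_lead, den_lag = i_lead, i_lag
    else:
        den_lead = den_lag = i_tot

    def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (num * c_scale) / (den * i_scale)
        out[den == 0] = np.nan
        return out

    return DensityProfile(
        window_offsets(flank, bin_size),
        _ratio(c_lead, den_lead),
        _ratio(c_lag, den_lag),
        _ratio(c_tot, i_tot),
    )
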