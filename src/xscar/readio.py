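"""Ingest aligned sequencing fragments and split them by mapping strand.

SCAR-seq libraries are strand-resolved: whether a deduplicated fragment maps
to the forward or the reverse reference strand tells which nascent daughter
strand it came from. This module reads fragments from 6-column BED or SAM/BAM
and applies the standard SAM-flag dichotomy (unmapped reads excluded, flag
bit 16 = reverse, otherwise forward), equivalent to splitting a BAM with
``samtools view -F 20`` / ``-f 16``.

Coordinates are 0-based half-open throughout. Duplicate removal and UMI
handling are assumed to have happened upstream, at alignment time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

FORWARD = "+"
REVERSE = "-"
_STRANDS = frozenset((FORWARD, REVERSE))
_FRAGMENT_COLUMNS = ("contig", "start", "end", "strand")


@dataclass(frozen=True)
class AlignedFragment:
    """A single mapped fragment: contig, [start, end) in bp, and strand."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid fragment interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class StrandedReadSet:
    """A collection of aligned fragments with per-fragment strand.

    Backed by a DataFrame with columns (contig, start, end, strand);
    ``library_size`` is always the fragment count.
    """

    df: pd.DataFrame = field(default_factory=lambda: _empty_frame())

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table lacks columns {missing}")
        df = df.loc[:, list(_FRAGMENT_COLUMNS)].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["contig"] = df["contig"].astype(str)
        df["strand"] = df["strand"].astype(str)
        if len(df):
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
                raise ValueError(f"invalid fragment interval at record {bad}")
            if not df["strand"].isin(list(_STRANDS)).all():
                raise ValueError("strand column must contain only '+' and '-'")
        self.df = df

    @classmethod
    def from_fragments(cls, fragments: Iterable[AlignedFragment]) -> "StrandedReadSet":
        rows = [(f.contig, f.start, f.end, f.strand) for f in fragments]
        return cls(pd.DataFrame(rows, columns=list(_FRAGMENT_COLUMNS)))

    @property
    def library_size(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def midpoints(self) -> np.ndarray:
        """Fragment midpoints, the single point used for all counting."""
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2)

    def sorted(self) -> "StrandedReadSet":
        out = self.df.sort_values(list(_FRAGMENT_COLUMNS), kind="mergesort")
        return StrandedReadSet(out.reset_index(drop=True))

    def subset_strand(self, strand: str) -> "StrandedReadSet":
        if strand not in _STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        return StrandedReadSet(self.df[self.df["strand"] == strand].reset_index(drop=True))


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {"contig": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=str)}
    )


def _check_contigs(df: pd.DataFrame, contig_lengths: Mapping[str, int] | None) -> None:
    if contig_lengths is None or not len(df):
        return
    known = set(contig_lengths)
    seen = set(df["contig"].unique())
    unknown = seen - known
    if unknown:
        raise ValueError(f"unknown contig(s) in alignment file: {sorted(unknown)}")


def _infer_format(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".bed",):
        return "bed"
    if ext in (".bam",):
        return "bam"
    if ext in (".sam",):
        return "sam"
    raise ValueError(f"cannot infer alignment format from {path!r}; pass format=")


def _read_bed(path: str | os.PathLike) -> pd.DataFrame:
    contigs: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            strand = fields[5]
            if strand not in _STRANDS:
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            if not (0 <= start < end):
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            contigs.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    return pd.DataFrame(
        {"contig": contigs, "start": np.asarray(starts, dtype=np.int64),
         "end": np.asarray(ends, dtype=np.int64), "strand": strands}
    )


def _read_sam(path: str | os.PathLike, fmt: str, pairing: str) -> pd.DataFrame:
    mode = "rb" if fmt == "bam" else "r"
    rows: list[tuple[str, int, int, str]] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue  # flag bit 4: excluded from both strands
            if pairing == "single":
                strand = REVERSE if read.is_reverse else FORWARD
                rows.append((read.reference_name, read.reference_start, read.reference_end, strand))
            else:
                # one fragment per properly-paired template, oriented by the
                # first-in-pair mate, spanning the whole template
                if not (read.is_paired and read.is_proper_pair and read.is_read1):
                    continue
                tlen = read.template_length
                if tlen == 0:
                    continue
                start = min(read.reference_start, read.next_reference_start)
                end = start + abs(tlen)
                strand = REVERSE if read.is_reverse else FORWARD
                rows.append((read.reference_name, start, end, strand))
    return pd.DataFrame(rows, columns=list(_FRAGMENT_COLUMNS))


def read_alignments(
    path: str | os.PathLike,
    format: str | None = None,
    pairing: str = "single",
    contig_lengths: Mapping[str, int] | None = None,
) -> StrandedReadSet:
    """Read aligned fragments from BED or SAM/BAM into a :class:`StrandedReadSet`.

    Parameters
    ----------
    path
        Alignment file. ``format`` is inferred from the extension if omitted.
    format
        One of ``bed``, ``sam``, ``bam``.
    pairing
        ``single``: each mapped record is one fragment (flag bit 16 sets the
        strand, unmapped records are dropped). ``paired``: one fragment per
        properly-paired template; strand of the first-in-pair mate, template
        span as coordinates.
    contig_lengths
        Optional genome declaration; fragments on contigs absent from it are
        rejected by name.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("bed", "sam", "bam"):
        raise ValueError(f"unknown alignment format {fmt!r}")
    if pairing not in ("single", "paired"):
        raise ValueError(f"pairing must be 'single' or 'paired', got {pairing!r}")
    if fmt == "bed":
        df = _read_bed(path)
    else:
        df = _read_sam(path, fmt, pairing)
    _check_contigs(df, contig_lengths)
    return StrandedReadSet(df)


def split_strands(reads: StrandedReadSet) -> tuple[StrandedReadSet, StrandedReadSet]:
    """Partition a read set into (forward, reverse) subsets.

    The partition is exhaustive and disjoint: the two library sizes always
    sum to the input library size.
    """
    return reads.subset_strand(FORWARD), reads.subset_strand(REVERSE)
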