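"""Synthetic genomes, origins, and stranded read sets with known segregation bias.

The simulator emulates the inputs of a strand-resolved nascent-chromatin
experiment so every downstream stage of the pipeline has ground truth:

* a small multi-contig genome (default: three contigs with the chromosome
  proportions of fission yeast at half scale);
* replication origins with heterogeneous firing-efficiency scores, well
  separated so their signal windows never overlap;
* replication fork directionality determined by the nearest origin — right
  of a center the leading strand is the forward reference strand;
* parental-histone ChIP fragments whose mapping strand is the leading strand
  of their midpoint with probability ``p_lead`` (the leading-strand
  segregation probability), new-histone fragments with the complementary
  bias ``1 - p_lead``;
* strand-balanced EdU input fragments placed uniformly genome-wide.

With this construction the expected partition on the right flank of an
origin is +(2·p_lead - 1) for the parental mark and the mirror image for
the new-histone mark, which is what the recovery tests check.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .origins import OriginSet, nearest_center_indices
from .readio import FORWARD, REVERSE, StrandedReadSet

#: origin centers are placed on this grid so they sit on bin boundaries of
#: the finest analysis bin
ORIGIN_GRID = 500


def _default_contigs() -> dict[str, int]:
    return {"chrI": 2_800_000, "chrII": 2_300_000, "chrIII": 1_200_000}


@dataclass
class SimConfig:
    """Parameters of one synthetic strand-resolved experiment.

    ``flank`` is the half-span of nascent signal around each origin:
    ChIP fragment midpoints fall within ±flank of their origin. Origins are
    spaced at least 4·flank apart, so adjacent signal windows are disjoint.
    """

    seed: int
    contig_lengths: dict[str, int] = field(default_factory=_default_contigs)
    n_origins: int = 4
    origin_score_range: tuple[float, float] = (5.0, 100.0)
    p_lead: float = 0.8
    n_chip_fragments: int = 200_000
    n_input_fragments: int = 50_000
    fragment_length: int = 150
    flank: int = 5000

    @property
    def min_spacing(self) -> int:
        return 4 * self.flank

    @property
    def edge_clearance(self) -> int:
        """Origin-to-contig-edge clearance, rounded up to the origin grid."""
        return math.ceil((self.flank + self.fragment_length) / ORIGIN_GRID) * ORIGIN_GRID

    def validate(self) -> None:
        if not (0.0 <= self.p_lead <= 1.0):
            raise ValueError(f"p_lead must be in [0, 1], got {self.p_lead}")
        for name in ("n_origins", "n_chip_fragments", "n_input_fragments", "fragment_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flank <= 0 or self.flank % ORIGIN_GRID:
            raise ValueError(f"flank must be a positive multiple of {ORIGIN_GRID} bp")
        if not self.contig_lengths:
            raise ValueError("contig_lengths must be non-empty")
        lo, hi = self.origin_score_range
        if not (lo <= hi):
            raise ValueError("origin_score_range must be (min, max) with min <= max")
        for contig, length in self.contig_lengths.items():
            if length <= 0:
                raise ValueError(f"contig {contig!r} has non-positive length")
            needed = 2 * self.edge_clearance + (self.n_origins - 1) * self.min_spacing
            if length < needed:
                raise ValueError(
                    f"contig {contig!r} too short for {self.n_origins} origins: "
                    f"needs >= {needed} bp at spacing {self.min_spacing}, has {length}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["origin_score_range"] = list(self.origin_score_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "origin_score_range" in d:
            d["origin_score_range"] = tuple(d["origin_score_range"])
        if "contig_lengths" in d:
            d["contig_lengths"] = {str(k): int(v) for k, v in dict(d["contig_lengths"]).items()}
        return cls(**d)


@dataclass
class ForkMap:
    """Fork directionality: every position belongs to its nearest origin.

    Right of that origin (offset >= 0) the fork moves rightward and the
    nascent leading strand maps to the forward reference strand; left of it,
    to the reverse strand. Positions equidistant from two origins are
    assigned to the leftmost.
    """

    centers: dict[str, np.ndarray]
    contig_lengths: dict[str, int]

    def assign(self, contig: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(nearest origin index, side) per position; side +1 = right, -1 = left."""
        if contig not in self.centers:
            raise ValueError(f"no origins on contig {contig!r}")
        c = self.centers[contig]
        idx = nearest_center_indices(c, positions)
        side = np.where(np.asarray(positions) >= c[idx], 1, -1)
        return idx, side

    def leading_strand(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Reference strand ('+'/'-') the leading nascent strand maps to."""
        _, side = self.assign(contig, positions)
        return np.where(side > 0, FORWARD, REVERSE)


def simulate_origins(config: SimConfig) -> OriginSet:
    """Draw ``n_origins`` per contig with uniform scores and guaranteed spacing.

    Centers lie on the :data:`ORIGIN_GRID`, keep ``edge_clearance`` from
    contig ends and at least ``4 * flank`` from each other. Deterministic
    given the config seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    lo_score, hi_score = config.origin_score_range
    rows = []
    for contig, length in config.contig_lengths.items():
        clearance = config.edge_clearance
        usable = length - 2 * clearance - (config.n_origins - 1) * config.min_spacing
        ngrid = usable // ORIGIN_GRID  # validate() guarantees usable >= 0
        u = np.sort(rng.integers(0, ngrid + 1, size=config.n_origins))
        centers = clearance + u * ORIGIN_GRID + np.arange(config.n_origins) * config.min_spacing
        scores = rng.uniform(lo_score, hi_score, size=config.n_origins)
        for c, s in zip(centers, scores):
            rows.append((contig, int(c), float(s)))
    df = pd.DataFrame(rows, columns=["contig", "center", "score"])
    return OriginSet(df, source=f"simulated(seed={config.seed})")


def build_fork_map(origins: OriginSet, contig_lengths: Mapping[str, int]) -> ForkMap:
    """Nearest-origin fork directionality over the declared genome."""
    centers: dict[str, np.ndarray] = {}
    for contig in contig_lengths:
        c = origins.centers(contig)
        if c.size == 0:
            raise ValueError(f"contig {contig!r} has no origin; cannot orient forks")
        centers[contig] = c
    return ForkMap(centers, dict(contig_lengths))


def _fragments_frame(
    contigs: np.ndarray, mids: np.ndarray, strands: np.ndarray, fragment_length: int
) -> pd.DataFrame:
    half = fragment_length // 2
    starts = mids - half
    return pd.DataFrame(
        {
            "contig": contigs,
            "start": starts.astype(np.int64),
            "end": (starts + fragment_length).astype(np.int64),
            "strand": strands,
        }
    )


def _simulate_chip(
    rng: np.random.Generator,
    config: SimConfig,
    forks: ForkMap,
    origin_df: pd.DataFrame,
    p_leading: float,
) -> StrandedReadSet:
    n = config.n_chip_fragments
    weights = origin_df["score"].to_numpy()
    weights = weights / weights.sum()  # fragment placement linear in firing score
    pick = rng.choice(len(origin_df), size=n, p=weights)
    offsets = rng.integers(-config.flank, config.flank, size=n)
    mids = origin_df["center"].to_numpy()[pick] + offsets
    contigs = origin_df["contig"].to_numpy()[pick]
    lead = np.empty(n, dtype="<U1")
    for contig in np.unique(contigs):
        mask = contigs == contig
        lead[mask] = forks.leading_strand(contig, mids[mask])
    to_leading = rng.random(n) < p_leading
    other = np.where(lead == FORWARD, REVERSE, FORWARD)
    strands = np.where(to_leading, lead, other)
    return StrandedReadSet(_fragments_frame(contigs, mids, strands, config.fragment_length))


def _simulate_input(rng: np.random.Generator, config: SimConfig) -> StrandedReadSet:
    n = config.n_input_fragments
    names = np.array(list(config.contig_lengths))
    lengths = np.array([config.contig_lengths[c] for c in names], dtype=float)
    pick = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    half = config.fragment_length // 2
    lo = half
    hi = lengths[pick].astype(np.int64) - (config.fragment_length - half)
    mids = rng.integers(lo, hi + 1)
    strands = np.where(rng.random(n) < 0.5, FORWARD, REVERSE)
    return StrandedReadSet(
        _fragments_frame(names[pick], mids, strands, config.fragment_length)
    )


def simulate_scar_experiment(
    config: SimConfig, forks: ForkMap, origins: OriginSet
) -> tuple[StrandedReadSet, StrandedReadSet, StrandedReadSet]:
    """Simulate (parental ChIP, new-histone ChIP, EdU input) read sets.

    ChIP fragment midpoints are drawn per origin with weight proportional to
    its firing score and uniformly within ±flank of its center. A parental
    fragment maps to the leading strand of its midpoint with probability
    ``p_lead``; a new-histone fragment with probability ``1 - p_lead``.
    Input fragments are strand-balanced and uniform genome-wide. The three
    sets use independent substreams of the config seed.
    """
    config.validate()
    origin_df = origins.df
    if not len(origin_df):
        raise ValueError("empty origin set")
    parental = _simulate_chip(
        np.random.default_rng([config.seed, 1]), config, forks, origin_df, config.p_lead
    )
    new = _simulate_chip(
        np.random.default_rng([config.seed, 2]), config, forks, origin_df, 1.0 - config.p_lead
    )
    input_reads = _simulate_input(np.random.default_rng([config.seed, 3]), config)
    return parental, new, input_reads


def write_reads(
    reads: StrandedReadSet,
    path: str | os.PathLike,
    format: str = "bed",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a read set as 6-column BED or single-end BAM (flags 0/16).

    Round-trips losslessly through :func:`xscar.readio.read_alignments`
    (contig, start, end, strand). BAM output needs ``contig_lengths`` for
    the header.
    """
    df = reads.df
    if format == "bed":
        with open(path, "w") as fh:
            for i, row in enumerate(df.itertuples(index=False)):
                fh.write(f"{row.contig}\t{row.start}\t{row.end}\tfrag{i}\t0\t{row.strand}\n")
    elif format == "bam":
        if contig_lengths is None:
            raise ValueError("BAM output requires contig_lengths for the header")
        names = list(contig_lengths)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(contig_lengths[c])} for c in names],
        }
        ref_id = {c: i for i, c in enumerate(names)}
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            for i, row in enumerate(df.itertuples(index=False)):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}"
                a.flag = 16 if row.strand == REVERSE else 0
                a.reference_id = ref_id[row.contig]
                a.reference_start = int(row.start)
                a.mapping_quality = 60
                a.cigartuples = [(0, int(row.end - row.start))]
                out.write(a)
    else:
        raise ValueError(f"unknown read format {format!r}")
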