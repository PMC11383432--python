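"""Run configuration for the pipeline: parameter presets, YAML I/O, validation.

Two parameter regimes are built in, matching the two organisms the assay is
run on: fission yeast (500 bp bins, blur half-window 5 bins) and mouse
embryonic stem cells (1 kb bins, half-window 30 bins). The preset coupling
bin_size 500 <-> half_window 5 and 1000 <-> 30 is applied whenever
``half_window`` is left unset; an explicit value always wins.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

_PRESET_HALF_WINDOW = {500: 5, 1000: 30}
CHEMISTRIES = ("standard", "mirrored-umi")


@dataclass
class RunConfig:
    """Configuration of a tracks/partition/aggregate run."""

    out_dir: str = "."
    # sample declarations: paths to aligned fragments
    parental: str | None = None
    new: str | None = None
    input: str | None = None
    format: str = "bed"           # bed | sam | bam
    pairing: str = "single"       # single | paired
    genome: str | None = None     # TSV of contig<TAB>length
    origins: str | None = None    # bedGraph-like origin list
    # library chemistry: mirrored-umi sequences the complementary strand and
    # needs the partition negated
    chemistry: str = "standard"
    bin_size: int = 500
    half_window: int | None = None
    min_origin_score: float = 20.0
    flank: int = 2500
    blur_input: bool = True
    density_input_stratification: str = "matching"  # matching | total
    orient: str = "signed"        # signed | leading
    seed: int | None = None
    log_level: str = "INFO"

    def resolve(self) -> "RunConfig":
        """Apply presets and validate; returns self for chaining."""
        if self.half_window is None:
            if self.bin_size not in _PRESET_HALF_WINDOW:
                raise ValueError(
                    f"no half_window preset for bin_size {self.bin_size}; set half_window"
                )
            self.half_window = _PRESET_HALF_WINDOW[self.bin_size]
        if self.half_window < 0:
            raise ValueError("half_window must be >= 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"chemistry must be one of {CHEMISTRIES}, got {self.chemistry!r}")
        if self.flank <= 0 or self.flank % self.bin_size:
            raise ValueError(
                f"flank ({self.flank}) must be a positive multiple of bin_size ({self.bin_size})"
            )
        if self.format not in ("bed", "sam", "bam"):
            raise ValueError(f"unknown alignment format {self.format!r}")
        if self.pairing not in ("single", "paired"):
            raise ValueError(f"pairing must be 'single' or 'paired', got {self.pairing!r}")
        if self.density_input_stratification not in ("matching", "total"):
            raise ValueError("density_input_stratification must be 'matching' or 'total'")
        if self.orient not in ("signed", "leading"):
            raise ValueError("orient must be 'signed' or 'leading'")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
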