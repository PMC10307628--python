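"""Domain records shared across the pipeline.

Conventions
-----------
* Genomic intervals are 0-based half-open.
* SNV positions are 1-based (VCF convention); they are converted exactly
  once, at the I/O boundary, when intersected with intervals.
* Breakend orientation: ``L`` means the segment to the LEFT (lower
  coordinate) of the position is retained/joined at the junction, ``R``
  means the segment to the RIGHT is retained. A deletion-like junction is
  (L, R); a duplication-like head-to-tail junction is (R, L) with
  pos1 < pos2; fold-back junctions are (L, L) or (R, R).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .genome import chrom_sort_key, normalize_chrom

ORIENTATIONS = ("L", "R")


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    orientation: str  # "L" or "R"

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be L or R, got {self.orientation!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")

    @property
    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.orientation)


@dataclass(frozen=True)
class SVRecord:
    """A structural variant: two oriented breakends plus supporting-fragment count."""

    sample: str
    breakend1: Breakend
    breakend2: Breakend
    support: int = 0
    id: str = ""

    def __post_init__(self):
        if self.support < 0:
            raise ValueError(f"SV {self.id or '<unnamed>'}: negative support {self.support}")
        if self.breakend2.sort_key < self.breakend1.sort_key:
            b1, b2 = self.breakend2, self.breakend1
            object.__setattr__(self, "breakend1", b1)
            object.__setattr__(self, "breakend2", b2)

    @property
    def is_intra(self) -> bool:
        return self.breakend1.chrom == self.breakend2.chrom

    @property
    def is_translocation(self) -> bool:
        return not self.is_intra

    @property
    def is_foldback(self) -> bool:
        """Same-orientation intra-chromosomal junction with breakends < 5 kb apart."""
        return (
            self.is_intra
            and self.breakend1.orientation == self.breakend2.orientation
            and abs(self.breakend1.pos - self.breakend2.pos) < 5_000
        )

    @property
    def chroms(self) -> frozenset[str]:
        return frozenset((self.breakend1.chrom, self.breakend2.chrom))


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific copy number over a half-open genomic interval."""

    sample: str
    chrom: str
    start: int
    end: int
    cn_total: float
    cn_major: float
    cn_minor: float

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.start < self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if min(self.cn_total, self.cn_major, self.cn_minor) < 0:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: negative CN")
        if self.cn_major < self.cn_minor:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"cn_major {self.cn_major} < cn_minor {self.cn_minor}"
            )
        if abs(self.cn_major + self.cn_minor - self.cn_total) > 0.1:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"cn_major + cn_minor = {self.cn_major + self.cn_minor:.3f} "
                f"inconsistent with cn_total = {self.cn_total:.3f}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SNVRecord:
    """A somatic SNV with allele depths. ``pos`` is 1-based."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    total_depth: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.total_depth <= 0:
            raise ValueError(f"SNV {self.chrom}:{self.pos}: non-positive depth")
        if not 0 <= self.alt_count <= self.total_depth:
            raise ValueError(
                f"SNV {self.chrom}:{self.pos}: alt_count {self.alt_count} "
                f"outside [0, depth={self.total_depth}]"
            )

    @property
    def vaf(self) -> float:
        return self.alt_count / self.total_depth


@dataclass(frozen=True)
class FeatureInterval:
    chrom: str
    start: int
    end: int
    score: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.start < self.end:
            raise ValueError(f"feature {self.chrom}:{self.start}-{self.end}: start >= end")
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError(f"feature {self.chrom}:{self.start}-{self.end}: non-finite score")


@dataclass
class FeatureTrack:
    """A named set of scored intervals (ChIP-seq peaks, signal bins, ...)."""

    name: str
    intervals: list[FeatureInterval] = field(default_factory=list)


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample manifest row. Flags are tri-valued (True/False/None=missing)."""

    sample: str
    purity: float
    ploidy: float = 2.0
    age: Optional[float] = None
    er_status: Optional[bool] = None
    hr_deficient: Optional[bool] = None
    wgd: Optional[bool] = None
    msi: Optional[bool] = None
    sbs2_13_fraction: Optional[float] = None
    snv_count: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError(f"sample {self.sample}: purity {self.purity} outside (0,1]")
        if self.ploidy <= 0:
            raise ValueError(f"sample {self.sample}: non-positive ploidy")
        if self.sbs2_13_fraction is not None and not 0 <= self.sbs2_13_fraction <= 1:
            raise ValueError(f"sample {self.sample}: sbs2_13_fraction outside [0,1]")


def sort_svs(svs: list[SVRecord]) -> list[SVRecord]:
    return sorted(svs, key=lambda s: (s.sample, s.breakend1.sort_key, s.breakend2.sort_key, s.id))


def sort_segments(segs: list[CopyNumberSegment]) -> list[CopyNumberSegment]:
    return sorted(segs, key=lambda s: (s.sample, chrom_sort_key(s.chrom), s.start))


__all__ = [
    "Breakend",
    "SVRecord",
    "CopyNumberSegment",
    "SNVRecord",
    "FeatureInterval",
    "FeatureTrack",
    "SampleInfo",
    "sort_svs",
    "sort_segments",
    "replace",
]
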