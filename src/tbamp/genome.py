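"""Genome layout: chromosome lengths, centromeres, and arm intervals.

Coordinates are 0-based, half-open throughout. Chromosome names are
normalized to bare names (``chr17`` -> ``17``) so that hg19-style and
hs37d5-style inputs mix freely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; ``chrX`` and ``X`` are the same chromosome."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise ValueError("empty chromosome name")
    return name


def chrom_sort_key(name: str):
    """Natural ordering: numeric chromosomes first, then X, Y, others lexically."""
    name = normalize_chrom(name)
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


@dataclass(frozen=True)
class Arm:
    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass
class GenomeLayout:
    """Ordered chromosomes with lengths and centromere intervals.

    Invariant: for every chromosome, ``p ∪ centromere ∪ q`` tiles
    ``[0, length)`` without overlap.
    """

    lengths: dict[str, int] = field(default_factory=dict)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = {normalize_chrom(c): int(n) for c, n in self.lengths.items()}
        self.centromeres = {
            normalize_chrom(c): (int(a), int(b)) for c, (a, b) in self.centromeres.items()
        }
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {n}")
            if chrom not in self.centromeres:
                raise ValueError(f"chromosome {chrom}: no centromere defined")
            a, b = self.centromeres[chrom]
            if not (0 < a < b < n):
                raise ValueError(
                    f"chromosome {chrom}: centromere [{a},{b}) not strictly inside [0,{n})"
                )

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.lengths, key=chrom_sort_key)

    def length(self, chrom: str) -> int:
        return self.lengths[normalize_chrom(chrom)]

    def centromere(self, chrom: str) -> tuple[int, int]:
        return self.centromeres[normalize_chrom(chrom)]

    def arm(self, chrom: str, arm: str) -> Arm:
        chrom = normalize_chrom(chrom)
        cen = self.centromeres[chrom]
        if arm == "p":
            return Arm(chrom, "p", 0, cen[0])
        if arm == "q":
            return Arm(chrom, "q", cen[1], self.lengths[chrom])
        raise ValueError(f"unknown arm {arm!r}")

    def arms(self) -> list[Arm]:
        out = []
        for chrom in self.chromosomes:
            out.append(self.arm(chrom, "p"))
            out.append(self.arm(chrom, "q"))
        return out

    def arm_of(self, chrom: str, pos: int) -> str:
        """Arm containing ``pos``; positions inside the centromere map to 'q'."""
        chrom = normalize_chrom(chrom)
        if not (0 <= pos < self.lengths[chrom]):
            raise ValueError(f"position {pos} outside chromosome {chrom}")
        return "p" if pos < self.centromeres[chrom][0] else "q"

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


_CYTOBAND_COLS = 5


def read_genome_layout(path: str | Path) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from a UCSC cytoBand-format file.

    The centromere is the union of the ``acen`` bands of each chromosome;
    the chromosome length is the maximum band end. A chromosome without an
    ``acen`` band is an error.
    """
    lengths: dict[str, int] = {}
    acen: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _CYTOBAND_COLS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_CYTOBAND_COLS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                chrom = normalize_chrom(fields[0])
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            stain = fields[4]
            lengths[chrom] = max(lengths.get(chrom, 0), end)
            if stain == "acen":
                acen.setdefault(chrom, []).append((start, end))
    if not lengths:
        raise ValueError(f"{path}: no cytoband records found")
    centromeres = {}
    for chrom in lengths:
        if chrom not in acen:
            raise ValueError(f"chromosome {chrom}: no acen (centromere) band in {path}")
        starts = [s for s, _ in acen[chrom]]
        ends = [e for _, e in acen[chrom]]
        centromeres[chrom] = (min(starts), max(ends))
    return GenomeLayout(lengths=lengths, centromeres=centromeres)


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    """Write a minimal cytoBand file: p band(s), two acen bands, q band(s)."""
    with open(path, "w") as fh:
        for chrom in layout.chromosomes:
            n = layout.length(chrom)
            a, b = layout.centromere(chrom)
            mid = (a + b) // 2
            fh.write(f"{chrom}\t0\t{a}\tp11\tgneg\n")
            fh.write(f"{chrom}\t{a}\t{mid}\tp10\tacen\n")
            fh.write(f"{chrom}\t{mid}\t{b}\tq10\tacen\n")
            fh.write(f"{chrom}\t{b}\t{n}\tq11\tgneg\n")
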