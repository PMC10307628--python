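"""Tab-delimited readers and writers for the pipeline's file formats.

Each reader is the inverse of the corresponding writer on valid data.
Formats: SEG-like copy-number TSV, BEDPE (strand "+" = orientation L,
"-" = orientation R), SNV TSV or VCF (AD-style allele depths), sample
manifest TSV, BED/bedGraph feature tracks, expression matrix TSV.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd

from .genome import GenomeLayout, chrom_sort_key
from .records import (
    Breakend,
    CopyNumberSegment,
    FeatureInterval,
    FeatureTrack,
    SampleInfo,
    SNVRecord,
    SVRecord,
    sort_segments,
    sort_svs,
)

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "cn_total", "cn_major", "cn_minor"]
SNV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "alt_count", "total_depth"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "sample", "support",
]
MANIFEST_COLUMNS = [
    "sample", "purity", "ploidy", "age", "er_status", "hr_deficient",
    "wgd", "msi", "sbs2_13_fraction", "snv_count",
]

_STRAND_TO_ORIENT = {"+": "L", "-": "R"}
_ORIENT_TO_STRAND = {"L": "+", "R": "-"}


# ---------------------------------------------------------------- segments

def read_cn_segments(
    path: str | Path, layout: Optional[GenomeLayout] = None
) -> list[CopyNumberSegment]:
    """Read allele-specific copy-number segments.

    Validates invariants, rejects chromosomes absent from ``layout``, and
    errors on overlapping segments within one sample/chromosome. Returns
    segments sorted by (sample, chromosome, start).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    segs = [
        CopyNumberSegment(
            sample=row.sample,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            cn_total=float(row.cn_total),
            cn_major=float(row.cn_major),
            cn_minor=float(row.cn_minor),
        )
        for row in df.itertuples(index=False)
    ]
    if layout is not None:
        known = set(layout.chromosomes)
        for s in segs:
            if s.chrom not in known:
                raise ValueError(f"{path}: unknown chromosome {s.chrom!r}")
            if s.end > layout.length(s.chrom):
                raise ValueError(
                    f"{path}: segment {s.chrom}:{s.start}-{s.end} extends past "
                    f"chromosome end {layout.length(s.chrom)}"
                )
    segs = sort_segments(segs)
    prev: Optional[CopyNumberSegment] = None
    for s in segs:
        if prev is not None and prev.sample == s.sample and prev.chrom == s.chrom:
            if s.start < prev.end:
                raise ValueError(
                    f"{path}: overlapping segments in sample {s.sample}: "
                    f"{s.chrom}:{prev.start}-{prev.end} and {s.chrom}:{s.start}-{s.end}"
                )
        prev = s
    return segs


def write_cn_segments(segs: list[CopyNumberSegment], path: str | Path) -> None:
    rows = [
        (s.sample, s.chrom, s.start, s.end,
         f"{s.cn_total:.4f}", f"{s.cn_major:.4f}", f"{s.cn_minor:.4f}")
        for s in sort_segments(segs)
    ]
    _write_tsv(path, SEGMENT_COLUMNS, rows)


# ------------------------------------------------------------------ BEDPE

def read_sv_bedpe(path: str | Path, support_column: str = "support") -> list[SVRecord]:
    """Read SVs from headered BEDPE.

    Strand "+" maps to orientation L (left side retained), "-" to R.
    Support is read from ``support_column``; if absent, support is 0 with a
    warning (classification remains possible without read support).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str, "sample": str})
    df.columns = [c.lstrip("#") for c in df.columns]
    required = ["chrom1", "start1", "chrom2", "start2", "strand1", "strand2"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing BEDPE columns {sorted(missing)}")
    has_support = support_column in df.columns
    if not has_support:
        warnings.warn(
            f"{path}: no {support_column!r} column; setting support=0", stacklevel=2
        )
    svs = []
    for i, row in enumerate(df.itertuples(index=False)):
        for strand in (row.strand1, row.strand2):
            if strand not in _STRAND_TO_ORIENT:
                raise ValueError(f"{path}: row {i}: invalid strand {strand!r}")
        support = int(getattr(row, support_column)) if has_support else 0
        svs.append(
            SVRecord(
                sample=str(getattr(row, "sample", "")) or "",
                breakend1=Breakend(row.chrom1, int(row.start1), _STRAND_TO_ORIENT[row.strand1]),
                breakend2=Breakend(row.chrom2, int(row.start2), _STRAND_TO_ORIENT[row.strand2]),
                support=support,
                id=str(getattr(row, "name", i)),
            )
        )
    return sort_svs(svs)


def write_sv_bedpe(svs: list[SVRecord], path: str | Path) -> None:
    rows = []
    for s in sort_svs(svs):
        b1, b2 = s.breakend1, s.breakend2
        rows.append(
            (b1.chrom, b1.pos, b1.pos + 1, b2.chrom, b2.pos, b2.pos + 1,
             s.id, ".", _ORIENT_TO_STRAND[b1.orientation],
             _ORIENT_TO_STRAND[b2.orientation], s.sample, s.support)
        )
    _write_tsv(path, BEDPE_COLUMNS, rows)


# ------------------------------------------------------------------- SNVs

def read_snv_table(path: str | Path) -> list[SNVRecord]:
    """Read SNVs from tab-delimited (``SNV_COLUMNS`` header) or VCF.

    VCF files (detected by extension or ``##fileformat`` header) take
    alt/total depths from the first sample's AD field.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or _looks_like_vcf(path):
        return _read_snv_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(SNV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return sorted(
        (
            SNVRecord(
                sample=row.sample, chrom=row.chrom, pos=int(row.pos),
                ref=row.ref, alt=row.alt,
                alt_count=int(row.alt_count), total_depth=int(row.total_depth),
            )
            for row in df.itertuples(index=False)
        ),
        key=lambda r: (r.sample, chrom_sort_key(r.chrom), r.pos),
    )


def _looks_like_vcf(path: Path) -> bool:
    try:
        with open(path) as fh:
            return fh.readline().startswith("##fileformat=VCF")
    except (OSError, UnicodeDecodeError):
        return False


def _read_snv_vcf(path: Path) -> list[SNVRecord]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    out = []
    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else ""
    for v in vcf:
        if not v.is_snp:
            continue
        ad = v.format("AD")
        if ad is None:
            continue
        ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
        out.append(
            SNVRecord(
                sample=sample, chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
                alt_count=alt_d, total_depth=ref_d + alt_d,
            )
        )
    return sorted(out, key=lambda r: (r.sample, chrom_sort_key(r.chrom), r.pos))


def write_snv_table(snvs: list[SNVRecord], path: str | Path) -> None:
    rows = [
        (r.sample, r.chrom, r.pos, r.ref, r.alt, r.alt_count, r.total_depth)
        for r in sorted(snvs, key=lambda r: (r.sample, chrom_sort_key(r.chrom), r.pos))
    ]
    _write_tsv(path, SNV_COLUMNS, rows)


# --------------------------------------------------------------- manifest

def _parse_flag(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and value != value) or value == "" or value == "NA":
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    if s in {"na", "nan", "none", "."}:
        return None
    raise ValueError(f"cannot parse flag value {value!r}")


def read_manifest(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns or "purity" not in df.columns:
        raise ValueError(f"{path}: manifest needs at least sample and purity columns")
    out = []
    for row in df.to_dict(orient="records"):
        def fnum(key, cast=float):
            v = row.get(key)
            if v is None or (isinstance(v, float) and v != v) or v in ("", "NA"):
                return None
            return cast(v)

        out.append(
            SampleInfo(
                sample=row["sample"],
                purity=float(row["purity"]),
                ploidy=fnum("ploidy") or 2.0,
                age=fnum("age"),
                er_status=_parse_flag(row.get("er_status")),
                hr_deficient=_parse_flag(row.get("hr_deficient")),
                wgd=_parse_flag(row.get("wgd")),
                msi=_parse_flag(row.get("msi")),
                sbs2_13_fraction=fnum("sbs2_13_fraction"),
                snv_count=fnum("snv_count", int),
            )
        )
    return sorted(out, key=lambda s: s.sample)


def write_manifest(samples: list[SampleInfo], path: str | Path) -> None:
    def flag(v):
        return "NA" if v is None else str(bool(v)).lower()

    rows = []
    for s in sorted(samples, key=lambda s: s.sample):
        rows.append(
            (s.sample, f"{s.purity:.4f}", f"{s.ploidy:.4f}",
             "NA" if s.age is None else f"{s.age:.2f}",
             flag(s.er_status), flag(s.hr_deficient), flag(s.wgd), flag(s.msi),
             "NA" if s.sbs2_13_fraction is None else f"{s.sbs2_13_fraction:.4f}",
             "NA" if s.snv_count is None else s.snv_count)
        )
    _write_tsv(path, MANIFEST_COLUMNS, rows)


# ----------------------------------------------------------------- tracks

def read_feature_track(path: str | Path, name: Optional[str] = None) -> FeatureTrack:
    """Read a BED (peaks; score 1.0) or bedGraph (4th column = score) track."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            score = 1.0
            if len(fields) >= 4:
                try:
                    score = float(fields[3])
                except ValueError:
                    score = 1.0  # BED name column
            intervals.append(
                FeatureInterval(fields[0], int(fields[1]), int(fields[2]), score)
            )
    return FeatureTrack(name=name or Path(path).stem, intervals=intervals)


def write_feature_track(track: FeatureTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(track.intervals, key=lambda v: (chrom_sort_key(v.chrom), v.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")


# ------------------------------------------------------------- expression

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes (rows) x samples (columns) expression matrix, TSV with index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ------------------------------------------------------------------ utils

def _write_tsv(path: str | Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)
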