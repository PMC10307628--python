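"""Arm-baseline estimation and focal amplicon calling.

An arm's baseline copy number is the integer copy number supported by the
largest combined span of segments on that arm (after rounding each
segment's total CN to the nearest integer, half up). Arms whose modal copy
number is haploid (or zero) are treated as diploid. A focal amplicon is a
run of contiguous segments whose total CN exceeds ``fold`` (default 3)
times the arm baseline; merged runs shorter than ``min_size`` (default
1 kb) are discarded. An amplicon flank is "unamplified" when the abutting
segment's rounded CN is at most one copy above the arm baseline; only
amplicons with at least one unamplified flank are eligible for boundary
analysis.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

from .genome import Arm, GenomeLayout
from .records import CopyNumberSegment

FLANK_UNAMPLIFIED = "unamplified"
FLANK_NOT_UNAMPLIFIED = "not_unamplified"
FLANK_CHROMOSOME_END = "chromosome_end"
FLANK_CENTROMERE = "centromere"


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ArmBaseline:
    sample: str
    chrom: str
    arm: str
    baseline: int
    supporting_span: int

    def __post_init__(self):
        if self.baseline < 2:
            raise ValueError("baseline below 2 should have been overridden to diploid")


@dataclass
class Amplicon:
    sample: str
    chrom: str
    arm: str
    start: int
    end: int
    mean_cn: float
    baseline: int
    left_flank: str = FLANK_NOT_UNAMPLIFIED
    right_flank: str = FLANK_NOT_UNAMPLIFIED
    left_neighbor_cn: Optional[float] = None
    right_neighbor_cn: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def eligible(self) -> bool:
        """Analysis-eligible: at least one flank borders an unamplified region."""
        return FLANK_UNAMPLIFIED in (self.left_flank, self.right_flank)


def _span_tally(segments: list[CopyNumberSegment]) -> dict[int, int]:
    tally: dict[int, int] = defaultdict(int)
    for s in segments:
        tally[round_half_up(s.cn_total)] += s.length
    return dict(tally)


def _baseline_from_tally(tally: dict[int, int]) -> tuple[int, int]:
    best_span = max(tally.values())
    # deterministic tie-break: the smallest integer CN among equal spans
    baseline = min(cn for cn, span in tally.items() if span == best_span)
    if baseline < 2:  # haploid (or lost) arms are treated as diploid
        baseline = 2
    return baseline, best_span


def estimate_arm_baseline(
    segments: list[CopyNumberSegment], sample: str, chrom: str, arm: str
) -> ArmBaseline:
    """Length-weighted modal integer CN of one arm's segments (diploid floor)."""
    if not segments:
        raise ValueError(f"no segments on arm {chrom}{arm} of sample {sample}")
    baseline, span = _baseline_from_tally(_span_tally(segments))
    return ArmBaseline(sample=sample, chrom=chrom, arm=arm, baseline=baseline, supporting_span=span)


def _clip_to_arm(seg: CopyNumberSegment, arm: Arm) -> Optional[CopyNumberSegment]:
    start, end = max(seg.start, arm.start), min(seg.end, arm.end)
    if start >= end:
        return None
    if (start, end) == (seg.start, seg.end):
        return seg
    return CopyNumberSegment(
        sample=seg.sample, chrom=seg.chrom, start=start, end=end,
        cn_total=seg.cn_total, cn_major=seg.cn_major, cn_minor=seg.cn_minor,
    )


def arm_baselines(
    segments: list[CopyNumberSegment], layout: GenomeLayout
) -> dict[tuple[str, str, str], ArmBaseline]:
    """Baselines for every (sample, chrom, arm) with data.

    Arms without segments inherit the whole-chromosome tally, so sparse
    profiles still yield a baseline for every arm of a covered chromosome.
    """
    by_sample_chrom: dict[tuple[str, str], list[CopyNumberSegment]] = defaultdict(list)
    for s in segments:
        by_sample_chrom[(s.sample, s.chrom)].append(s)
    out: dict[tuple[str, str, str], ArmBaseline] = {}
    for (sample, chrom), segs in by_sample_chrom.items():
        for arm_name in ("p", "q"):
            arm = layout.arm(chrom, arm_name)
            clipped = [c for s in segs if (c := _clip_to_arm(s, arm)) is not None]
            if clipped:
                out[(sample, chrom, arm_name)] = estimate_arm_baseline(
                    clipped, sample, chrom, arm_name
                )
            else:
                baseline, span = _baseline_from_tally(_span_tally(segs))
                out[(sample, chrom, arm_name)] = ArmBaseline(
                    sample=sample, chrom=chrom, arm=arm_name,
                    baseline=baseline, supporting_span=span,
                )
    return out


def call_amplicons(
    segments: list[CopyNumberSegment],
    baselines: dict[tuple[str, str, str], ArmBaseline],
    layout: GenomeLayout,
    min_size: int = 1_000,
    fold: float = 3.0,
    merge_gap: int = 0,
    flank_margin: int = 1,
) -> list[Amplicon]:
    """Call focal amplicons: segments with cn_total > fold x arm baseline,
    merged when within ``merge_gap`` bp, dropped when shorter than
    ``min_size``. Flanks are classified in the same pass."""
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = defaultdict(list)
    for s in segments:
        by_key[(s.sample, s.chrom)].append(s)
    out: list[Amplicon] = []
    for (sample, chrom), segs in sorted(by_key.items()):
        segs = sorted(segs, key=lambda s: s.start)
        for arm_name in ("p", "q"):
            arm = layout.arm(chrom, arm_name)
            key = (sample, chrom, arm_name)
            if key not in baselines:
                continue
            baseline = baselines[key].baseline
            clipped = [c for s in segs if (c := _clip_to_arm(s, arm)) is not None]
            selected = [s for s in clipped if s.cn_total > fold * baseline]
            if not selected:
                continue
            # merge runs of selected segments separated by <= merge_gap
            runs: list[list[CopyNumberSegment]] = [[selected[0]]]
            for s in selected[1:]:
                if s.start - runs[-1][-1].end <= merge_gap:
                    runs[-1].append(s)
                else:
                    runs.append([s])
            for run in runs:
                start, end = run[0].start, run[-1].end
                if end - start < min_size:
                    continue
                total = sum(s.length for s in run)
                mean_cn = sum(s.cn_total * s.length for s in run) / total
                amp = Amplicon(
                    sample=sample, chrom=chrom, arm=arm_name,
                    start=start, end=end, mean_cn=mean_cn, baseline=baseline,
                )
                classify_flanks(amp, clipped, baseline, arm, flank_margin)
                out.append(amp)
    return out


def classify_flanks(
    amplicon: Amplicon,
    arm_segments: list[CopyNumberSegment],
    baseline: int,
    arm: Arm,
    flank_margin: int = 1,
) -> Amplicon:
    """Label each flank of an amplicon (in place) and record neighbour CN.

    A flank is ``unamplified`` iff the abutting segment's rounded total CN
    is at most ``baseline + flank_margin``. When no segment abuts on a
    side, the flank is the structural boundary the amplicon runs into:
    the telomere (``chromosome_end``) or the ``centromere``.
    """
    def structural(side: str) -> str:
        # left side of a p-arm amplicon faces the telomere; of a q-arm, the centromere
        if side == "left":
            return FLANK_CHROMOSOME_END if arm.arm == "p" else FLANK_CENTROMERE
        return FLANK_CENTROMERE if arm.arm == "p" else FLANK_CHROMOSOME_END

    left = next((s for s in arm_segments if s.end == amplicon.start), None)
    right = next((s for s in arm_segments if s.start == amplicon.end), None)
    if left is None:
        amplicon.left_flank = structural("left")
    else:
        amplicon.left_neighbor_cn = left.cn_total
        amplicon.left_flank = (
            FLANK_UNAMPLIFIED
            if round_half_up(left.cn_total) <= baseline + flank_margin
            else FLANK_NOT_UNAMPLIFIED
        )
    if right is None:
        amplicon.right_flank = structural("right")
    else:
        amplicon.right_neighbor_cn = right.cn_total
        amplicon.right_flank = (
            FLANK_UNAMPLIFIED
            if round_half_up(right.cn_total) <= baseline + flank_margin
            else FLANK_NOT_UNAMPLIFIED
        )
    return amplicon
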