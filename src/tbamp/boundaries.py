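"""Matching SVs to amplicon edges and classifying the boundary taxonomy.

Each eligible amplicon edge is matched against breakends within a
tolerance that also point into the amplicon (left edge: orientation R,
right edge: orientation L — the retained side is the amplified one).
Matched edges are classified into six categories: fold-back inversion
(same-orientation intra-chromosomal junction < 5 kb apart, the BFB
hallmark), translocation (inter-chromosomal, the TB hallmark), double
minute / tandem duplication (one head-to-tail junction spanning both
edges, split at 3x the adjacent segment's CN), intra-chromosomal complex,
and no SV support. The per-amplicon category is the highest-precedence
edge category.

The amplified-SV support threshold is the inflection of the sorted
support curve: the support value at the largest positive second forward
difference (fallback: twice the sample median).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .amplicons import Amplicon, round_half_up
from .records import Breakend, SVRecord

CAT_FOLD_BACK = "fold_back"
CAT_TRANSLOCATION = "translocation"
CAT_DOUBLE_MINUTE = "double_minute"
CAT_TANDEM_DUPLICATION = "tandem_duplication"
CAT_INTRA_COMPLEX = "intra_complex"
CAT_NO_SV = "no_sv_support"

#: precedence order, mechanism-diagnostic categories first
CATEGORY_PRECEDENCE = [
    CAT_FOLD_BACK,
    CAT_TRANSLOCATION,
    CAT_DOUBLE_MINUTE,
    CAT_TANDEM_DUPLICATION,
    CAT_INTRA_COMPLEX,
    CAT_NO_SV,
]

_EDGE_ORIENTATION = {"left": "R", "right": "L"}


@dataclass(frozen=True)
class EdgeMatch:
    sv: SVRecord
    breakend: Breakend
    distance: int


@dataclass
class BoundaryCall:
    amplicon: Amplicon
    edge: str  # "left" or "right"
    sv: Optional[SVRecord]
    category: str

    def __post_init__(self):
        if (self.category == CAT_NO_SV) != (self.sv is None):
            raise ValueError("category is no_sv_support iff no SV is attached")


@dataclass
class AmpliconClassification:
    amplicon: Amplicon
    left: BoundaryCall
    right: BoundaryCall
    category: str

    @property
    def boundary_svs(self) -> list[SVRecord]:
        return [c.sv for c in (self.left, self.right) if c.sv is not None]


def match_boundary_svs(
    amplicon: Amplicon, svs: list[SVRecord], tolerance_bp: int = 1_000
) -> dict[str, list[EdgeMatch]]:
    """Candidate SVs per edge, ranked by support (desc) then distance (asc).

    A breakend matches an edge iff it lies within ``tolerance_bp`` of the
    edge position and its orientation retains the amplified side.
    """
    edges = {"left": amplicon.start, "right": amplicon.end}
    out: dict[str, list[EdgeMatch]] = {"left": [], "right": []}
    for edge, pos in edges.items():
        want = _EDGE_ORIENTATION[edge]
        for sv in svs:
            if sv.sample != amplicon.sample:
                continue
            for be in (sv.breakend1, sv.breakend2):
                if be.chrom != amplicon.chrom or be.orientation != want:
                    continue
                dist = abs(be.pos - pos)
                if dist <= tolerance_bp:
                    out[edge].append(EdgeMatch(sv=sv, breakend=be, distance=dist))
        out[edge].sort(key=lambda m: (-m.sv.support, m.distance, m.sv.id))
    return out


def _spanning_head_to_tail(matches: dict[str, list[EdgeMatch]]) -> list[SVRecord]:
    """Intra-chromosomal (R, L) SVs whose two breakends match BOTH edges:
    the self-ligation signature of a circularized or tandem-duplicated segment."""
    left_ids = {m.sv.id: m.sv for m in matches["left"] if m.breakend is m.sv.breakend1}
    out = []
    for m in matches["right"]:
        sv = m.sv
        if (
            sv.id in left_ids
            and sv.is_intra
            and sv.breakend1.orientation == "R"
            and sv.breakend2.orientation == "L"
            and m.breakend is sv.breakend2
        ):
            out.append(sv)
    return out


def _adjacent_cn(amplicon: Amplicon) -> float:
    """Rounded CN of the segment(s) abutting the amplicon (max of the two
    sides; the arm baseline when both flanks are structural boundaries)."""
    vals = [
        cn for cn in (amplicon.left_neighbor_cn, amplicon.right_neighbor_cn) if cn is not None
    ]
    if not vals:
        return float(amplicon.baseline)
    return float(max(round_half_up(v) for v in vals))


def classify_amplicon(
    amplicon: Amplicon,
    matches: dict[str, list[EdgeMatch]],
    foldback_window: int = 5_000,
    dm_fold: float = 3.0,
) -> AmpliconClassification:
    """Classify each edge and the amplicon; precedence is total, so every
    amplicon receives exactly one category."""
    spanning = _spanning_head_to_tail(matches)
    adjacent = max(_adjacent_cn(amplicon), 1.0)
    calls: dict[str, BoundaryCall] = {}
    for edge in ("left", "right"):
        cands = matches[edge]
        foldbacks = [
            m for m in cands
            if m.sv.is_intra
            and m.sv.breakend1.orientation == m.sv.breakend2.orientation
            and abs(m.sv.breakend1.pos - m.sv.breakend2.pos) < foldback_window
        ]
        translocations = [m for m in cands if m.sv.is_translocation]
        if foldbacks:
            calls[edge] = BoundaryCall(amplicon, edge, foldbacks[0].sv, CAT_FOLD_BACK)
        elif translocations:
            calls[edge] = BoundaryCall(amplicon, edge, translocations[0].sv, CAT_TRANSLOCATION)
        elif spanning:
            cat = (
                CAT_DOUBLE_MINUTE
                if amplicon.mean_cn > dm_fold * adjacent
                else CAT_TANDEM_DUPLICATION
            )
            calls[edge] = BoundaryCall(amplicon, edge, spanning[0], cat)
        elif cands:
            calls[edge] = BoundaryCall(amplicon, edge, cands[0].sv, CAT_INTRA_COMPLEX)
        else:
            calls[edge] = BoundaryCall(amplicon, edge, None, CAT_NO_SV)
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    category = min((calls["left"].category, calls["right"].category), key=rank.__getitem__)
    return AmpliconClassification(
        amplicon=amplicon, left=calls["left"], right=calls["right"], category=category
    )


def classify_boundaries(
    amplicons: list[Amplicon],
    svs: list[SVRecord],
    tolerance_bp: int = 1_000,
    foldback_window: int = 5_000,
    dm_fold: float = 3.0,
    eligible_only: bool = True,
) -> list[AmpliconClassification]:
    """Match and classify every (eligible) amplicon of a cohort."""
    by_sample: dict[str, list[SVRecord]] = defaultdict(list)
    for sv in svs:
        by_sample[sv.sample].append(sv)
    out = []
    for amp in amplicons:
        if eligible_only and not amp.eligible:
            continue
        m = match_boundary_svs(amp, by_sample.get(amp.sample, []), tolerance_bp)
        out.append(classify_amplicon(amp, m, foldback_window, dm_fold))
    return out


# ------------------------------------------------ amplified-SV threshold

@dataclass
class SupportThreshold:
    threshold: Optional[float]
    amplified_ids: frozenset[str]
    used_fallback: bool = False

    def is_amplified(self, sv: SVRecord) -> bool:
        return sv.id in self.amplified_ids


def amplified_sv_threshold(svs: list[SVRecord], min_svs: int = 5) -> SupportThreshold:
    """Tumour-specific support threshold at the inflection of the sorted
    support curve (largest positive second forward difference)."""
    positive = [sv for sv in svs if sv.support > 0]
    if len(positive) < min_svs:
        warnings.warn(
            f"fewer than {min_svs} SVs with positive support; nothing flagged amplified",
            stacklevel=2,
        )
        return SupportThreshold(threshold=None, amplified_ids=frozenset())
    s = np.sort([sv.support for sv in positive])
    d2 = s[2:] - 2 * s[1:-1] + s[:-2]
    used_fallback = False
    if d2.size and d2.max() > 0:
        threshold = float(s[int(np.argmax(d2)) + 2])
    else:
        threshold = 2.0 * float(np.median(s))
        used_fallback = True
    amplified = frozenset(sv.id for sv in positive if sv.support >= threshold)
    return SupportThreshold(threshold=threshold, amplified_ids=amplified, used_fallback=used_fallback)


# ------------------------------------------------------ pan-cancer views

def cohort_category_matrix(
    classifications: list[AmpliconClassification],
    tumour_types: dict[str, str],
    min_amplicons: int = 10,
) -> pd.DataFrame:
    """Per-tumour-type fractions of amplicon-level boundary categories.

    Types with fewer than ``min_amplicons`` classified amplicons are
    excluded with a warning. Returns a DataFrame indexed by tumour type
    with one column per category plus ``n_amplicons``.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for c in classifications:
        ttype = tumour_types.get(c.amplicon.sample)
        if ttype is None:
            continue
        counts[ttype][c.category] += 1
    rows = {}
    for ttype, cat_counts in sorted(counts.items()):
        n = sum(cat_counts.values())
        if n < min_amplicons:
            warnings.warn(
                f"tumour type {ttype!r}: only {n} amplicons (< {min_amplicons}); excluded",
                stacklevel=2,
            )
            continue
        row = {cat: cat_counts.get(cat, 0) / n for cat in CATEGORY_PRECEDENCE}
        row["n_amplicons"] = n
        rows[ttype] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def cluster_tumour_types(matrix: pd.DataFrame, k: int = 4) -> pd.Series:
    """Agglomerative (average-linkage, Euclidean) clustering of tumour types
    on their fold-back / translocation / double-minute fractions, cut at k."""
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} tumour types, got {len(matrix)}")
    feats = matrix[[CAT_FOLD_BACK, CAT_TRANSLOCATION, CAT_DOUBLE_MINUTE]].to_numpy(float)
    link = sch.linkage(feats, method="average", metric="euclidean")
    labels = sch.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="group")
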