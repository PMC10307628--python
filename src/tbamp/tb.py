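"""Rearrangement clustering and translocation-bridge (TB) footprint detection.

SVs are clustered by a simplified phasing rule set (breakend proximity on a
chromosome, translocations sharing an arm pair, fold-backs sharing an arm).
A cluster is a TB-amplification footprint when it has >= 10 SVs, involves
multiple chromosomes, and contains at least one amplicon-boundary
translocation. Bridge arms — the arms carrying boundary-translocation
breakends — are annotated with their telomeric loss-of-heterozygosity
(LOH) run; the model predicts telomeric LOH on both bridge arms (dual-LOH)
with heterozygosity retained on the non-bridge arms.

When scanning the telomeric LOH run, focally amplified segments
(total CN > 3x the arm baseline) do not interrupt the run: the amplified
copies are extrachromosomal or ectopic, so the chromosomal locus under an
amplicon embedded in an LOH span is itself hemizygous.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .amplicons import ArmBaseline, arm_baselines
from .boundaries import CAT_TRANSLOCATION, AmpliconClassification
from .genome import GenomeLayout, chrom_sort_key
from .records import CopyNumberSegment, SVRecord


@dataclass
class SVCluster:
    sample: str
    svs: list[SVRecord]

    @property
    def n_sv(self) -> int:
        return len(self.svs)

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(c for sv in self.svs for c in sv.chroms)

    @property
    def translocations(self) -> list[SVRecord]:
        return [sv for sv in self.svs if sv.is_translocation]


@dataclass
class TBEvent:
    cluster: SVCluster
    bridge_arms: list[tuple[str, str]]
    loh_fractions: dict[tuple[str, str], float]
    dual_loh: bool
    non_bridge_sv_counts: dict[str, int]
    boundary_translocations: list[SVRecord] = field(default_factory=list)
    extensive: bool = False
    round_id: Optional[int] = None

    @property
    def sample(self) -> str:
        return self.cluster.sample


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_svs(
    svs: list[SVRecord], layout: GenomeLayout, proximity_bp: int = 5_000_000
) -> list[SVCluster]:
    """Union-find over three merge rules:

    (a) two breakends on the same chromosome within ``proximity_bp``;
    (b) translocations joining the same (unordered) pair of chromosome arms;
    (c) all fold-back inversions on one arm.
    """
    by_sample: dict[str, list[SVRecord]] = defaultdict(list)
    for sv in svs:
        by_sample[sv.sample].append(sv)
    clusters: list[SVCluster] = []
    for sample in sorted(by_sample):
        sample_svs = sorted(
            by_sample[sample], key=lambda s: (s.breakend1.sort_key, s.breakend2.sort_key, s.id)
        )
        uf = _UnionFind(len(sample_svs))
        # rule (a): proximity of breakends on a chromosome
        per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for i, sv in enumerate(sample_svs):
            for be in (sv.breakend1, sv.breakend2):
                per_chrom[be.chrom].append((be.pos, i))
        for chrom, items in per_chrom.items():
            items.sort()
            for (pos_a, ia), (pos_b, ib) in zip(items, items[1:]):
                if pos_b - pos_a <= proximity_bp:
                    uf.union(ia, ib)
        # rule (b): translocations sharing an arm pair
        arm_pairs: dict[tuple, list[int]] = defaultdict(list)
        for i, sv in enumerate(sample_svs):
            if sv.is_translocation:
                a1 = (sv.breakend1.chrom, layout.arm_of(sv.breakend1.chrom, sv.breakend1.pos))
                a2 = (sv.breakend2.chrom, layout.arm_of(sv.breakend2.chrom, sv.breakend2.pos))
                arm_pairs[tuple(sorted((a1, a2)))].append(i)
        # rule (c): fold-backs on one arm
        foldback_arms: dict[tuple, list[int]] = defaultdict(list)
        for i, sv in enumerate(sample_svs):
            if sv.is_foldback:
                arm = (sv.breakend1.chrom, layout.arm_of(sv.breakend1.chrom, sv.breakend1.pos))
                foldback_arms[arm].append(i)
        for group in list(arm_pairs.values()) + list(foldback_arms.values()):
            for j in group[1:]:
                uf.union(group[0], j)
        members: dict[int, list[SVRecord]] = defaultdict(list)
        for i, sv in enumerate(sample_svs):
            members[uf.find(i)].append(sv)
        clusters.extend(SVCluster(sample=sample, svs=m) for _, m in sorted(members.items()))
    return clusters


def telomeric_loh_fraction(
    segments: list[CopyNumberSegment],
    layout: GenomeLayout,
    chrom: str,
    arm: str,
    loh_minor_max: float = 0.25,
    amp_fold: float = 3.0,
    baseline: int = 2,
) -> float:
    """Fraction of the arm covered by the maximal run of minor-CN-zero
    segments ending at the telomere. Focally amplified segments (total CN
    > ``amp_fold`` x ``baseline``) neither extend nor interrupt the run."""
    arm_iv = layout.arm(chrom, arm)
    if arm_iv.length <= 0:
        return 0.0
    segs = sorted(
        (s for s in segments if s.chrom == chrom and s.end > arm_iv.start and s.start < arm_iv.end),
        key=lambda s: s.start,
    )
    if arm == "q":
        segs = segs[::-1]  # walk inward from the telomere
    run = 0
    for s in segs:
        start, end = max(s.start, arm_iv.start), min(s.end, arm_iv.end)
        if s.cn_total > amp_fold * baseline:
            continue
        if s.cn_minor <= loh_minor_max:
            run += end - start
        else:
            break
    return run / arm_iv.length


def detect_tb_events(
    clusters: list[SVCluster],
    classifications: list[AmpliconClassification],
    segments: list[CopyNumberSegment],
    layout: GenomeLayout,
    min_sv: int = 10,
    loh_minor_max: float = 0.25,
    amp_fold: float = 3.0,
    baselines: Optional[dict[tuple[str, str, str], ArmBaseline]] = None,
) -> list[TBEvent]:
    """TB footprints: multi-chromosome clusters of >= ``min_sv`` SVs that
    contain at least one amplicon-boundary translocation."""
    if baselines is None:
        baselines = arm_baselines(segments, layout)
    boundary_tra: dict[str, dict[str, SVRecord]] = defaultdict(dict)
    for c in classifications:
        for call in (c.left, c.right):
            if call.category == CAT_TRANSLOCATION and call.sv is not None:
                boundary_tra[c.amplicon.sample][call.sv.id] = call.sv
    seg_by_sample: dict[str, list[CopyNumberSegment]] = defaultdict(list)
    for s in segments:
        seg_by_sample[s.sample].append(s)
    events: list[TBEvent] = []
    for cluster in clusters:
        if cluster.n_sv < min_sv or len(cluster.chromosomes) < 2:
            continue
        member_ids = {sv.id for sv in cluster.svs}
        btras = [
            sv for svid, sv in sorted(boundary_tra.get(cluster.sample, {}).items())
            if svid in member_ids
        ]
        if not btras:
            continue
        bridge_arms = sorted(
            {
                (be.chrom, layout.arm_of(be.chrom, be.pos))
                for sv in btras
                for be in (sv.breakend1, sv.breakend2)
            },
            key=lambda a: (chrom_sort_key(a[0]), a[1]),
        )
        sample_segs = seg_by_sample.get(cluster.sample, [])
        fractions = {}
        non_bridge_counts: dict[str, int] = {}
        for chrom, arm in bridge_arms:
            bl = baselines.get((cluster.sample, chrom, arm))
            fractions[(chrom, arm)] = telomeric_loh_fraction(
                sample_segs, layout, chrom, arm,
                loh_minor_max=loh_minor_max, amp_fold=amp_fold,
                baseline=bl.baseline if bl else 2,
            )
            opposite = "q" if arm == "p" else "p"
            opp_iv = layout.arm(chrom, opposite)
            non_bridge_counts[chrom] = sum(
                1
                for sv in cluster.svs
                for be in (sv.breakend1, sv.breakend2)
                if be.chrom == chrom and opp_iv.start <= be.pos < opp_iv.end
            )
        chroms_with_loh = {chrom for (chrom, arm), f in fractions.items() if f > 0}
        event = TBEvent(
            cluster=cluster,
            bridge_arms=bridge_arms,
            loh_fractions=fractions,
            dual_loh=len(chroms_with_loh) >= 2,
            non_bridge_sv_counts=non_bridge_counts,
            boundary_translocations=btras,
        )
        event.extensive = flag_extensive(event)
        events.append(event)
    return events


def flag_extensive(event: TBEvent, min_translocations: int = 10) -> bool:
    """Extensive TB footprint: >= 10 translocations between the involved chromosomes."""
    involved = event.cluster.chromosomes
    n = sum(1 for sv in event.cluster.translocations if sv.chroms <= involved)
    return n >= min_translocations


def partition_rounds(events: list[TBEvent]) -> list[TBEvent]:
    """Assign round IDs to one sample's TB events.

    Chromosomes are graph nodes; each event's cluster translocations are
    edges. Rounds are the connected components: events whose chromosome
    sets fall in different components were independent amplification
    rounds (no intermingled translocations).
    """
    if not events:
        return events
    parents: dict[str, str] = {}

    def find(x: str) -> str:
        parents.setdefault(x, x)
        while parents[x] != x:
            parents[x] = parents[parents[x]]
            x = parents[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parents[rb] = ra

    for ev in events:
        chroms = sorted(ev.cluster.chromosomes, key=chrom_sort_key)
        for c in chroms:
            find(c)
        for sv in ev.cluster.translocations:
            union(sv.breakend1.chrom, sv.breakend2.chrom)
        # an event's own chromosomes always belong to one round
        for c in chroms[1:]:
            union(chroms[0], c)
    roots: dict[str, int] = {}
    for ev in sorted(
        events, key=lambda e: sorted(chrom_sort_key(c) for c in e.cluster.chromosomes)
    ):
        root = find(sorted(ev.cluster.chromosomes, key=chrom_sort_key)[0])
        ev.round_id = roots.setdefault(root, len(roots) + 1)
    return events


def cohort_association(
    alterations: pd.DataFrame,
    tb_labels: pd.Series,
    gene_classes: Optional[dict[str, str]] = None,
    top_fraction: float = 0.10,
    min_frequency: float = 0.05,
    q_threshold: float = 0.10,
) -> pd.DataFrame:
    """Case-control screen of gene alterations against extensive-TB status.

    Per alteration class, the top ``top_fraction`` most frequently altered
    genes are kept; genes altered in under ``min_frequency`` of samples are
    dropped. Each remaining gene gets a two-sided Fisher's exact test and
    Benjamini-Hochberg q-value (significant at q < ``q_threshold``).
    Odds ratios for degenerate tables use the Haldane 0.5 correction and
    are flagged.
    """
    alterations = alterations.astype(bool)
    tb = tb_labels.reindex(alterations.index).astype(bool)
    n_samples = len(alterations)
    freqs = alterations.sum(axis=0)
    classes = gene_classes or {g: "all" for g in alterations.columns}
    keep: list[str] = []
    for cls in sorted(set(classes.values())):
        genes = [g for g in alterations.columns if classes.get(g, "all") == cls]
        if not genes:
            continue
        k = max(1, int(np.ceil(top_fraction * len(genes))))
        ranked = freqs[genes].sort_values(ascending=False, kind="stable")
        keep.extend(ranked.index[:k])
    rows = []
    for gene in keep:
        if freqs[gene] / n_samples < min_frequency:
            continue
        altered = alterations[gene]
        a = int((altered & tb).sum())
        b = int((altered & ~tb).sum())
        c = int((~altered & tb).sum())
        d = int((~altered & ~tb).sum())
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        haldane = 0 in (a, b, c, d)
        if haldane:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            dict(gene=gene, n_altered=int(freqs[gene]), odds_ratio=float(odds),
                 p=float(p), haldane=haldane)
        )
    df = pd.DataFrame(rows, columns=["gene", "n_altered", "odds_ratio", "p", "haldane"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values(["q", "p", "gene"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
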