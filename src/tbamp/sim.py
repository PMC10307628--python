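"""Generative models of focal-amplification mechanisms with ground truth.

The translocation-bridge (TB) generator follows the dicentric model: a G1
translocation joins the distal ends of two oncogene-bearing q arms into a
dicentric chromosome (the distal acentric pieces are lost); after
replication the two sister dicentrics align anti-parallel in a chromosome
bridge and each breaks once between the centromeres; the daughter cell
inheriting the two complementary hemi-dicentrics shows telomeric LOH on
both bridge arms with heterozygosity retained on the non-bridge arms
(the dual-LOH footprint), and the oncogene-bearing fragments between the
two sister breakpoints circularize into extrachromosomal DNA amplified to
tens of copies, with read-amplified boundary translocations.

Breakage-fusion-bridge (chromatid type) produces stair-step copy gains
with fold-back inversions; chromothripsis produces oscillating single-
chromosome fragmentation; tandem duplications and simple double minutes
produce one head-to-tail junction each. A clock process deposits SNVs per
haplotype before and after each event, recording per-SNV multiplicity
truth. All draws flow through one ``numpy.random.Generator``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genome import GenomeLayout
from .records import (
    Breakend,
    CopyNumberSegment,
    FeatureInterval,
    FeatureTrack,
    SampleInfo,
    SNVRecord,
    SVRecord,
)

MB = 1_000_000

MECH_TB = "TB"
MECH_BFB = "BFB"
MECH_CHROMOTHRIPSIS = "chromothripsis"
MECH_TANDEM_DUP = "tandem_dup"
MECH_SIMPLE_DM = "simple_DM"
MECHANISMS = (MECH_TB, MECH_BFB, MECH_CHROMOTHRIPSIS, MECH_TANDEM_DUP, MECH_SIMPLE_DM)


# ----------------------------------------------------------------- config

@dataclass
class SimConfig:
    """Study conditions for the simulator. Defaults are the conditions the
    pipeline is validated under; see the methods note for rationale."""

    n_chromosomes: int = 8
    max_chrom_mb: float = 200.0
    chrom_step_mb: float = 12.0
    centromere_fraction: float = 0.4
    centromere_mb: float = 3.0
    #: oncogene position as a fraction of the q arm (distal placement keeps
    #: uniform bridge breakage <-> ~50% mean bridge-arm LOH)
    oncogene_arm_fraction: float = 0.95
    purity: float = 0.7
    depth: int = 60
    #: diploid clock: 29.4 clonal SNVs/yr over a 2,880-Mb genome
    clock_rate_per_mb_yr: float = 29.4 / 2880.0
    subclonal_per_mb: float = 0.05
    age_mean: float = 55.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (30.0, 80.0)
    # TB event
    amp_width_mb: tuple[float, float] = (0.5, 2.0)
    ecdna_cn_range: tuple[float, float] = (10.0, 100.0)
    boundary_support_per_copy: float = 3.0
    internal_sv_mean: float = 20.0
    extra_bridge_translocations_mean: float = 3.0
    non_bridge_gain_prob: float = 0.5
    #: years between bridge breakage and the non-bridge arm gain
    gain_delay_years: tuple[float, float] = (0.0, 5.0)
    chain_length: int = 2
    # BFB
    bfb_cycles: tuple[int, int] = (3, 5)
    # chromothripsis
    chromothripsis_fragments: tuple[int, int] = (12, 25)
    # background rearrangements
    background_sv_mean: float = 25.0
    background_support_mean: float = 9.0
    # measurement noise
    cn_noise_sd: float = 0.05
    sv_jitter_bp: int = 60
    # planted breakpoint-propensity track
    propensity_weight: float = 0.0
    track_bin_kb: int = 100
    n_decoy_tracks: int = 5
    decoy_correlation: float = 0.2
    #: planted mode: boundary loci roam the genome instead of fixed oncogenes
    randomize_boundaries: bool = False
    # fixed event timing (None: drawn as a fraction of patient age)
    event_age: Optional[float] = None


def make_layout(config: SimConfig) -> GenomeLayout:
    lengths, cents = {}, {}
    for i in range(config.n_chromosomes):
        n = int((config.max_chrom_mb - config.chrom_step_mb * i) * MB)
        c0 = int(n * config.centromere_fraction)
        cents[str(i + 1)] = (c0, c0 + int(config.centromere_mb * MB))
        lengths[str(i + 1)] = n
    return GenomeLayout(lengths=lengths, centromeres=cents)


def oncogene_positions(config: SimConfig, layout: GenomeLayout) -> dict[str, int]:
    """Default oncogene locus per chromosome: a point on the q arm."""
    out = {}
    for chrom in layout.chromosomes:
        arm = layout.arm(chrom, "q")
        out[chrom] = arm.start + int(config.oncogene_arm_fraction * arm.length)
    return out


# ------------------------------------------------------ propensity track

@dataclass
class PropensityTrack:
    """Per-bin breakpoint propensity in [0, 1]; breakpoints are drawn with
    probability proportional to 1 + w * score."""

    layout: GenomeLayout
    bin_bp: int
    scores: dict[str, np.ndarray]
    weight: float = 0.0

    def score_at(self, chrom: str, pos: int) -> float:
        arr = self.scores[chrom]
        return float(arr[min(pos // self.bin_bp, len(arr) - 1)])

    def draw_position(self, rng: np.random.Generator, chrom: str, lo: int, hi: int) -> int:
        """One position in [lo, hi) ~ (1 + w * score), uniform within a bin."""
        if hi <= lo:
            raise ValueError("empty interval")
        if self.weight == 0.0:
            return int(rng.integers(lo, hi))
        b0, b1 = lo // self.bin_bp, (hi - 1) // self.bin_bp + 1
        arr = self.scores[chrom][b0:b1]
        starts = (np.arange(b0, b1) * self.bin_bp).clip(lo, hi)
        ends = ((np.arange(b0, b1) + 1) * self.bin_bp).clip(lo, hi)
        widths = (ends - starts).astype(float)
        w = (1.0 + self.weight * arr) * widths
        w_sum = w.sum()
        if w_sum <= 0:
            return int(rng.integers(lo, hi))
        k = int(rng.choice(len(w), p=w / w_sum))
        return int(rng.integers(starts[k], ends[k]))

    def to_feature_track(self, name: str = "propensity") -> FeatureTrack:
        ivs = []
        for chrom in self.layout.chromosomes:
            arr = self.scores[chrom]
            n = self.layout.length(chrom)
            for i, s in enumerate(arr):
                ivs.append(
                    FeatureInterval(chrom, i * self.bin_bp,
                                    min((i + 1) * self.bin_bp, n), float(s))
                )
        return FeatureTrack(name=name, intervals=ivs)


def make_propensity_track(
    config: SimConfig, layout: GenomeLayout, rng: np.random.Generator
) -> PropensityTrack:
    """Blocky random track: ~15% of 1-Mb blocks carry elevated propensity."""
    bin_bp = config.track_bin_kb * 1000
    scores = {}
    for chrom in layout.chromosomes:
        n_bins = math.ceil(layout.length(chrom) / bin_bp)
        block = 10  # 1-Mb blocks of 100-kb bins
        n_blocks = math.ceil(n_bins / block)
        hot = rng.random(n_blocks) < 0.15
        level = rng.uniform(0.5, 1.0, size=n_blocks) * hot
        scores[chrom] = np.repeat(level, block)[:n_bins]
    return PropensityTrack(layout=layout, bin_bp=bin_bp, scores=scores,
                           weight=config.propensity_weight)


def make_decoy_tracks(
    track: PropensityTrack, config: SimConfig, rng: np.random.Generator
) -> list[PropensityTrack]:
    """Decoy features: mildly correlated with the planted track."""
    rho = config.decoy_correlation
    out = []
    for _ in range(config.n_decoy_tracks):
        scores = {}
        for chrom, arr in track.scores.items():
            noise = rng.random(len(arr)) * (rng.random(len(arr)) < 0.15)
            scores[chrom] = np.clip(rho * arr + (1 - rho) * noise, 0, 1)
        out.append(PropensityTrack(track.layout, track.bin_bp, scores, 0.0))
    return out


# ------------------------------------------------------- allele profiles

@dataclass
class _Zone:
    start: int
    end: int
    a: float  # copies of the rearranged haplotype
    age: Optional[float]  # age (years) of the CN-changing event, None = unchanged
    tag: str = "base"


class HaplotypeProfile:
    """Piecewise copy number of the rearranged haplotype per chromosome.

    The other haplotype stays at one copy everywhere; emitted segments are
    (major, minor) = (max(a, 1), min(a, 1)).
    """

    def __init__(self, layout: GenomeLayout):
        self.layout = layout
        self.zones: dict[str, list[_Zone]] = {
            c: [_Zone(0, layout.length(c), 1.0, None)] for c in layout.chromosomes
        }

    def set_interval(self, chrom: str, start: int, end: int, a: float,
                     age: Optional[float], tag: str) -> None:
        if not 0 <= start < end <= self.layout.length(chrom):
            raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome")
        new: list[_Zone] = []
        for z in self.zones[chrom]:
            if z.end <= start or z.start >= end:
                new.append(z)
                continue
            if z.start < start:
                new.append(_Zone(z.start, start, z.a, z.age, z.tag))
            if z.end > end:
                new.append(_Zone(end, z.end, z.a, z.age, z.tag))
        new.append(_Zone(start, end, a, age, tag))
        self.zones[chrom] = sorted(new, key=lambda z: z.start)

    def iter_zones(self):
        for chrom in self.layout.chromosomes:
            for z in self.zones[chrom]:
                yield chrom, z

    def to_segments(self, sample: str, rng: np.random.Generator,
                    noise_sd: float) -> list[CopyNumberSegment]:
        segs = []
        for chrom, z in self.iter_zones():
            major, minor = max(z.a, 1.0), min(z.a, 1.0)
            minor_n = max(0.0, minor + rng.normal(0, noise_sd))
            major_n = max(minor_n, major + rng.normal(0, noise_sd))
            segs.append(
                CopyNumberSegment(
                    sample=sample, chrom=chrom, start=z.start, end=z.end,
                    cn_total=major_n + minor_n, cn_major=major_n, cn_minor=minor_n,
                )
            )
        return segs


# ----------------------------------------------------------- sim results

@dataclass
class SimEvent:
    mechanism: str
    chromosomes: list[str]
    age: float
    bridge_arms: list[tuple[str, str]] = field(default_factory=list)
    gain_age: Optional[float] = None
    ecdna_cn: Optional[float] = None
    amplicons: list[tuple[str, int, int]] = field(default_factory=list)
    extensive: bool = False


@dataclass
class SimSample:
    info: SampleInfo
    segments: list[CopyNumberSegment]
    svs: list[SVRecord]
    snvs: list[SNVRecord]
    events: list[SimEvent]
    sv_labels: dict[str, str]
    snv_labels: dict[tuple[str, int], dict]

    @property
    def sample(self) -> str:
        return self.info.sample


@dataclass
class Cohort:
    config: SimConfig
    layout: GenomeLayout
    samples: list[SimSample]
    track: Optional[PropensityTrack] = None
    decoys: list[PropensityTrack] = field(default_factory=list)

    @property
    def segments(self) -> list[CopyNumberSegment]:
        return [s for smp in self.samples for s in smp.segments]

    @property
    def svs(self) -> list[SVRecord]:
        return [s for smp in self.samples for s in smp.svs]

    @property
    def snvs(self) -> list[SNVRecord]:
        return [s for smp in self.samples for s in smp.snvs]

    @property
    def manifest(self) -> list[SampleInfo]:
        return [s.info for s in self.samples]


# ------------------------------------------------------------- machinery

class _Builder:
    """Accumulates one sample's profile, SVs and truth labels."""

    def __init__(self, sample: str, config: SimConfig, layout: GenomeLayout,
                 rng: np.random.Generator, track: Optional[PropensityTrack]):
        self.sample = sample
        self.config = config
        self.layout = layout
        self.rng = rng
        self.track = track
        self.profile = HaplotypeProfile(layout)
        self.svs: list[SVRecord] = []
        self.sv_labels: dict[str, str] = {}
        self.events: list[SimEvent] = []
        self._n_sv = 0

    def draw_pos(self, chrom: str, lo: int, hi: int) -> int:
        if self.track is not None and self.track.weight != 0:
            return self.track.draw_position(self.rng, chrom, lo, hi)
        return int(self.rng.integers(lo, hi))

    def add_sv(self, c1: str, p1: int, o1: str, c2: str, p2: int, o2: str,
               support: int, label: str, jitter: bool = True) -> SVRecord:
        if jitter:
            j = self.config.sv_jitter_bp
            p1 += int(self.rng.integers(-j, j + 1))
            p2 += int(self.rng.integers(-j, j + 1))
        self._n_sv += 1
        sv = SVRecord(
            sample=self.sample,
            breakend1=Breakend(c1, max(p1, 0), o1),
            breakend2=Breakend(c2, max(p2, 0), o2),
            support=max(int(support), 1),
            id=f"{self.sample}_sv{self._n_sv:04d}",
        )
        self.svs.append(sv)
        self.sv_labels[sv.id] = label
        return sv

    def background_support(self) -> int:
        return 1 + int(self.rng.poisson(self.config.background_support_mean))


def _draw_ecdna_cn(config: SimConfig, rng: np.random.Generator) -> float:
    lo, hi = config.ecdna_cn_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_tb(b: _Builder, age: float, chroms: Sequence[str],
                oncogenes: dict[str, int],
                extensive: bool = False,
                force_non_bridge_gain: Optional[bool] = None) -> SimEvent:
    """One TB amplification: dicentric over the q arms of ``chroms`` (a
    chain longer than two is resolved to a dicentric over the first and
    last chromosome, with balanced chain translocations in between)."""
    cfg, rng, layout = b.config, b.rng, b.layout
    if len(chroms) < 2:
        raise ValueError("TB amplification needs at least two chromosomes")
    ca, cb = chroms[0], chroms[-1]
    tb_age = cfg.event_age if cfg.event_age is not None else float(rng.uniform(0.3, 0.7) * age)

    def arm_geometry(chrom: str) -> tuple[int, int, int]:
        """(amplicon start, translocation breakpoint, q-arm start)."""
        arm = layout.arm(chrom, "q")
        width = int(rng.uniform(*cfg.amp_width_mb) * MB)
        if cfg.randomize_boundaries:
            bx = b.draw_pos(chrom, arm.start + width + 5 * MB, arm.end - MB)
        else:
            onc = oncogenes[chrom]
            bx = onc + int(rng.uniform(0.05, 0.5) * MB)
            width = (bx - onc) + int(rng.uniform(0.2, 1.5) * MB)
        return bx - width, bx, arm.start

    for _ in range(100):
        a_lo, bx_a, qa = arm_geometry(ca)
        b_lo, bx_b, qb = arm_geometry(cb)
        if a_lo > qa + MB and b_lo > qb + MB:
            break
    else:
        raise RuntimeError("could not place TB amplicons on the bridge arms")

    len_a, len_b = bx_a - qa, bx_b - qb
    total = len_a + len_b
    # one bridge breakpoint per sister dicentric, uniform between the
    # centromeres; the emitted daughter requires the sister-1 break on the
    # A side (proximal of the A amplicon) and the sister-2 break on the B
    # side, which is what produces the dual-LOH pattern. The conditional
    # of two independent uniforms under these interval constraints is
    # itself uniform on each interval, so draw directly.
    c1 = float(rng.uniform(0, a_lo - qa))
    c2 = float(rng.uniform(len_a + (bx_b - b_lo), total))

    k = _draw_ecdna_cn(cfg, rng)
    kept_a = qa + int(c1)
    kept_b = qb + int(total - c2)
    tel_a, tel_b = layout.length(ca), layout.length(cb)
    # bridge arm A: retained het, LOH, amplicon, LOH-to-telomere
    b.profile.set_interval(ca, kept_a, tel_a, 0.0, tb_age, "loh")
    b.profile.set_interval(ca, a_lo, bx_a, k, tb_age, "ecdna")
    b.profile.set_interval(cb, kept_b, tel_b, 0.0, tb_age, "loh")
    b.profile.set_interval(cb, b_lo, bx_b, k, tb_age, "ecdna")

    support = int(cfg.boundary_support_per_copy * k + rng.poisson(3))
    # original G1 translocation junction (distal amplicon edges)
    b.add_sv(ca, bx_a, "L", cb, bx_b, "L", support, "tb_boundary")
    # ecDNA circularization junction (proximal amplicon edges)
    b.add_sv(ca, a_lo, "R", cb, b_lo, "R", support, "tb_boundary")

    # chain translocations for chromoplexy-style initiation (balanced)
    for x, y in zip(chroms, chroms[1:]):
        if {x, y} == {ca, cb}:
            continue
        px = b.draw_pos(x, layout.arm(x, "q").start + MB, layout.length(x) - MB)
        py = b.draw_pos(y, layout.arm(y, "q").start + MB, layout.length(y) - MB)
        b.add_sv(x, px, "L", y, py, "R", b.background_support(), "tb_chain")

    # dense, unamplified rearrangements internal to the circularized segment
    n_internal = int(rng.poisson(cfg.internal_sv_mean))
    margin = 5_000
    for _ in range(n_internal):
        chrom, lo, hi = (ca, a_lo, bx_a) if rng.random() < 0.5 else (cb, b_lo, bx_b)
        if hi - lo <= 2 * margin + 2:
            continue
        p1 = int(rng.integers(lo + margin, hi - margin))
        p2 = int(rng.integers(lo + margin, hi - margin))
        o1, o2 = rng.choice(["L", "R"], size=2)
        b.add_sv(chrom, p1, o1, chrom, p2, o2, b.background_support(), "tb_internal")

    # additional translocations between the bridge arms
    n_extra = (
        10 + int(rng.poisson(3))
        if extensive
        else int(rng.poisson(cfg.extra_bridge_translocations_mean))
    )
    for _ in range(n_extra):
        pa = int(rng.integers(kept_a + 1, tel_a - 1)) if tel_a - kept_a > 2 else kept_a
        pb = int(rng.integers(kept_b + 1, tel_b - 1)) if tel_b - kept_b > 2 else kept_b
        o1, o2 = rng.choice(["L", "R"], size=2)
        b.add_sv(ca, pa, o1, cb, pb, o2, b.background_support(), "tb_bridge_extra")

    gain_age = None
    do_gain = (
        force_non_bridge_gain
        if force_non_bridge_gain is not None
        else bool(rng.random() < cfg.non_bridge_gain_prob)
    )
    if do_gain:
        gain_age = min(float(tb_age + rng.uniform(*cfg.gain_delay_years)), age)
        for chrom in (ca, cb):
            p_end = layout.centromere(chrom)[0]
            b.profile.set_interval(chrom, 0, p_end, 2.0, gain_age, "gain")

    ev = SimEvent(
        mechanism=MECH_TB, chromosomes=list(chroms), age=tb_age,
        bridge_arms=[(ca, "q"), (cb, "q")], gain_age=gain_age, ecdna_cn=k,
        amplicons=[(ca, a_lo, bx_a), (cb, b_lo, bx_b)], extensive=extensive,
    )
    b.events.append(ev)
    return ev


def simulate_bfb(b: _Builder, age: float, chrom: str,
                 oncogenes: dict[str, int]) -> SimEvent:
    """Chromatid-type breakage-fusion-bridge: stair-step gains toward the
    oncogene with fold-back inversions and single-arm telomeric LOH."""
    cfg, rng, layout = b.config, b.rng, b.layout
    n_cycles = int(rng.integers(cfg.bfb_cycles[0], cfg.bfb_cycles[1] + 1))
    if n_cycles < 1:
        raise ValueError("BFB needs at least one cycle")
    ev_age = cfg.event_age if cfg.event_age is not None else float(rng.uniform(0.3, 0.7) * age)
    arm = layout.arm(chrom, "q")
    if cfg.randomize_boundaries:
        onc = b.draw_pos(chrom, arm.start + 12 * MB, arm.end - 3 * MB)
    else:
        onc = oncogenes[chrom]
    t0 = onc + int(rng.uniform(0.1, 1.0) * MB)
    breaks = [onc - int(rng.uniform(0.2, 1.0) * MB)]
    for _ in range(n_cycles - 1):
        nxt = max(breaks[-1] - int(rng.uniform(1, 5) * MB), arm.start + MB)
        if nxt >= breaks[-1]:
            nxt = breaks[-1] - MB
        breaks.append(nxt)
    # breaks[0] is the most recent (amplicon edge); deeper breaks are earlier
    tel = layout.length(chrom)
    b.profile.set_interval(chrom, t0, tel, 0.0, ev_age, "loh")
    for i, pos in enumerate(breaks):
        copies = float(2 ** (n_cycles - i))
        hi = t0 if i == 0 else breaks[i - 1]
        b.profile.set_interval(chrom, pos, hi, copies, ev_age, "bfb_step")
        orient = "R"  # proximal fold-backs retain the amplified (distal) side
        delta = int(rng.integers(200, 3_000))
        support = int(cfg.boundary_support_per_copy * copies + rng.poisson(3))
        b.add_sv(chrom, pos, orient, chrom, pos + delta, orient, support, "bfb_foldback")
    # terminal fusion fold-back at the original break
    delta = int(rng.integers(200, 3_000))
    support = int(cfg.boundary_support_per_copy * (2**n_cycles) + rng.poisson(3))
    b.add_sv(chrom, max(t0 - delta, breaks[0] + 1), "L", chrom, t0, "L",
             support, "bfb_foldback")
    # a handful of accompanying local rearrangements
    for _ in range(int(rng.poisson(6))):
        p1 = int(rng.integers(breaks[-1], t0))
        p2 = int(rng.integers(breaks[-1], t0))
        o1, o2 = rng.choice(["L", "R"], size=2)
        b.add_sv(chrom, p1, o1, chrom, p2, o2, b.background_support(), "bfb_internal")
    ev = SimEvent(
        mechanism=MECH_BFB, chromosomes=[chrom], age=ev_age,
        amplicons=[(chrom, breaks[0], t0)], ecdna_cn=float(2**n_cycles),
    )
    b.events.append(ev)
    return ev


def simulate_chromothripsis(b: _Builder, age: float, chrom: str) -> SimEvent:
    """Massive localized fragmentation on one chromosome: oscillating CN
    (retained/lost fragments) and dense intra-chromosomal junctions."""
    cfg, rng, layout = b.config, b.rng, b.layout
    ev_age = cfg.event_age if cfg.event_age is not None else float(rng.uniform(0.3, 0.7) * age)
    arm = layout.arm(chrom, "q")
    n_frag = int(rng.integers(*cfg.chromothripsis_fragments))
    edges = np.sort(rng.integers(arm.start + MB, arm.end - MB, size=n_frag - 1))
    bounds = [arm.start, *map(int, edges), arm.end]
    retained = rng.random(len(bounds) - 1) < 0.5
    for (lo, hi), keep in zip(zip(bounds, bounds[1:]), retained):
        if not keep and hi > lo:
            b.profile.set_interval(chrom, lo, hi, 0.0, ev_age, "ct_lost")
    for e in map(int, edges):
        o1, o2 = rng.choice(["L", "R"], size=2)
        partner = int(rng.choice(edges))
        b.add_sv(chrom, e, o1, chrom, partner, o2, b.background_support(), "ct_junction")
    ev = SimEvent(mechanism=MECH_CHROMOTHRIPSIS, chromosomes=[chrom], age=ev_age)
    b.events.append(ev)
    return ev


def simulate_tandem_dup(b: _Builder, age: float, chrom: str) -> SimEvent:
    """Multi-copy tandem duplication: amplicon over 3x the arm baseline but
    within 3x its (also duplicated) neighbourhood."""
    cfg, rng, layout = b.config, b.rng, b.layout
    ev_age = cfg.event_age if cfg.event_age is not None else float(rng.uniform(0.3, 0.7) * age)
    arm = layout.arm(chrom, "q")
    width = int(rng.uniform(*cfg.amp_width_mb) * MB)
    s = b.draw_pos(chrom, arm.start + 6 * MB, arm.end - 6 * MB - width)
    e = s + width
    flank = int(rng.uniform(1.0, 3.0) * MB)
    b.profile.set_interval(chrom, s - flank, s, 2.0, ev_age, "td_flank")
    b.profile.set_interval(chrom, e, e + flank, 2.0, ev_age, "td_flank")
    b.profile.set_interval(chrom, s, e, 6.0, ev_age, "td_amp")
    support = int(cfg.boundary_support_per_copy * 6 + rng.poisson(3))
    b.add_sv(chrom, s, "R", chrom, e, "L", support, "td_junction")
    ev = SimEvent(mechanism=MECH_TANDEM_DUP, chromosomes=[chrom], age=ev_age,
                  amplicons=[(chrom, s, e)])
    b.events.append(ev)
    return ev


def simulate_simple_dm(b: _Builder, age: float, chrom: str) -> SimEvent:
    """Simple double minute: self-ligation of one unrearranged segment,
    amplified far beyond its unamplified neighbourhood."""
    cfg, rng, layout = b.config, b.rng, b.layout
    ev_age = cfg.event_age if cfg.event_age is not None else float(rng.uniform(0.3, 0.7) * age)
    arm = layout.arm(chrom, "q")
    width = int(rng.uniform(*cfg.amp_width_mb) * MB)
    s = b.draw_pos(chrom, arm.start + 6 * MB, arm.end - 6 * MB - width)
    e = s + width
    k = _draw_ecdna_cn(cfg, rng)
    b.profile.set_interval(chrom, s, e, k, ev_age, "dm_amp")
    support = int(cfg.boundary_support_per_copy * k + rng.poisson(3))
    b.add_sv(chrom, s, "R", chrom, e, "L", support, "dm_junction")
    ev = SimEvent(mechanism=MECH_SIMPLE_DM, chromosomes=[chrom], age=ev_age,
                  amplicons=[(chrom, s, e)], ecdna_cn=k)
    b.events.append(ev)
    return ev


def simulate_other(b: _Builder, age: float, mechanism: str, chrom: str) -> SimEvent:
    if mechanism == MECH_CHROMOTHRIPSIS:
        return simulate_chromothripsis(b, age, chrom)
    if mechanism == MECH_TANDEM_DUP:
        return simulate_tandem_dup(b, age, chrom)
    if mechanism == MECH_SIMPLE_DM:
        return simulate_simple_dm(b, age, chrom)
    raise ValueError(f"unknown mechanism {mechanism!r}")


def _add_background_svs(b: _Builder) -> None:
    cfg, rng, layout = b.config, b.rng, b.layout
    n = int(rng.poisson(cfg.background_sv_mean))
    chroms = layout.chromosomes
    for _ in range(n):
        if rng.random() < 0.85:  # intra-chromosomal
            chrom = str(rng.choice(chroms))
            p1 = b.draw_pos(chrom, MB, layout.length(chrom) - MB)
            p2 = min(p1 + int(rng.uniform(0.01, 5) * MB), layout.length(chrom) - 1)
            o1, o2 = ("L", "R") if rng.random() < 0.5 else ("R", "L")
        else:
            chrom, chrom2 = rng.choice(chroms, size=2, replace=False)
            chrom, chrom2 = str(chrom), str(chrom2)
            p1 = b.draw_pos(chrom, MB, layout.length(chrom) - MB)
            p2 = b.draw_pos(chrom2, MB, layout.length(chrom2) - MB)
            b.add_sv(chrom, p1, str(rng.choice(["L", "R"])),
                     chrom2, p2, str(rng.choice(["L", "R"])),
                     b.background_support(), "background")
            continue
        b.add_sv(chrom, p1, o1, chrom, p2, o2, b.background_support(), "background")


# ------------------------------------------------------------------ SNVs

_BASES = np.array(list("ACGT"))


def simulate_snvs(b: _Builder, age: float) -> tuple[list[SNVRecord], dict]:
    """Clock SNVs per haplotype per zone with multiplicity truth.

    Mutations on the rearranged haplotype before a gain are carried by all
    gained copies (multiplicity = final copies); later mutations, and all
    mutations on the intact haplotype, sit on one copy. A small subclonal
    admixture is drawn at half a copy's expected VAF.
    """
    cfg, rng = b.config, b.rng
    half_rate = cfg.clock_rate_per_mb_yr / 2.0  # per-haplotype rate
    snvs: list[SNVRecord] = []
    labels: dict[tuple[str, int], dict] = {}

    def emit(chrom: str, lo: int, hi: int, copies: float, cn_total: float,
             n: int, label: str):
        if n <= 0:
            return
        positions = rng.integers(lo + 1, hi + 1, size=n)  # 1-based
        v = copies * cfg.purity / (cfg.purity * cn_total + 2 * (1 - cfg.purity))
        alts = rng.binomial(cfg.depth, min(v, 1.0), size=n)
        for pos, alt in zip(positions, alts):
            if alt == 0:
                continue
            ref, var = rng.choice(4, size=2, replace=False)
            rec = SNVRecord(
                sample=b.sample, chrom=chrom, pos=int(pos),
                ref=str(_BASES[ref]), alt=str(_BASES[var]),
                alt_count=int(alt), total_depth=cfg.depth,
            )
            snvs.append(rec)
            labels[(chrom, int(pos))] = dict(
                label=label, multiplicity=float(copies), cn_total=float(cn_total),
            )

    for chrom, z in b.profile.iter_zones():
        l_mb = (z.end - z.start) / MB
        cn_total = z.a + 1.0
        # intact haplotype: one copy everywhere, always multiplicity 1
        n = rng.poisson(half_rate * age * l_mb)
        emit(chrom, z.start, z.end, 1.0, cn_total, n, "clonal")
        # rearranged haplotype
        if z.age is None:
            n = rng.poisson(half_rate * age * l_mb)
            emit(chrom, z.start, z.end, 1.0, cn_total, n, "clonal")
        else:
            if z.a >= 1:
                n_pre = rng.poisson(half_rate * z.age * l_mb)
                pre_label = "pre_gain" if z.a >= 2 else "clonal"
                emit(chrom, z.start, z.end, z.a, cn_total, n_pre, pre_label)
                n_post = rng.poisson(half_rate * (age - z.age) * l_mb * z.a)
                emit(chrom, z.start, z.end, 1.0, cn_total, n_post, "post_gain")
            # z.a == 0: the haplotype is lost, its mutations are unobservable
        n_sub = rng.poisson(cfg.subclonal_per_mb * l_mb)
        emit(chrom, z.start, z.end, 0.5, cn_total, n_sub, "subclonal")
    return snvs, labels


# ----------------------------------------------------------- sample/cohort

def simulate_sample(
    config: SimConfig,
    layout: GenomeLayout,
    rng: np.random.Generator,
    sample: str,
    mechanism: str,
    track: Optional[PropensityTrack] = None,
    oncogenes: Optional[dict[str, int]] = None,
    extensive: bool = False,
    force_non_bridge_gain: Optional[bool] = None,
    with_snvs: bool = True,
) -> SimSample:
    """One tumour genome with a single driver event plus background."""
    if oncogenes is None:
        oncogenes = oncogene_positions(config, layout)
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), *config.age_range))
    b = _Builder(sample, config, layout, rng, track)
    chroms = layout.chromosomes
    if mechanism == MECH_TB:
        n_chain = max(2, config.chain_length)
        picked = [str(c) for c in rng.choice(chroms, size=n_chain, replace=False)]
        simulate_tb(b, age, picked, oncogenes, extensive=extensive,
                    force_non_bridge_gain=force_non_bridge_gain)
    elif mechanism == MECH_BFB:
        simulate_bfb(b, age, str(rng.choice(chroms)), oncogenes)
    else:
        simulate_other(b, age, mechanism, str(rng.choice(chroms)))
    _add_background_svs(b)
    if with_snvs:
        snvs, snv_labels = simulate_snvs(b, age)
    else:
        snvs, snv_labels = [], {}
    segments = b.profile.to_segments(sample, rng, config.cn_noise_sd)
    info = SampleInfo(
        sample=sample, purity=config.purity, age=age,
        er_status=bool(rng.random() < 0.7), hr_deficient=False,
        wgd=False, msi=False,
        sbs2_13_fraction=float(rng.uniform(0, 0.3)),
        snv_count=len(snvs),
    )
    return SimSample(
        info=info, segments=segments, svs=b.svs, snvs=snvs,
        events=b.events, sv_labels=b.sv_labels, snv_labels=snv_labels,
    )


def simulate_cohort(
    config: SimConfig,
    seed: int,
    n_samples: int,
    mechanism_mix: Optional[dict[str, float]] = None,
    with_snvs: bool = False,
) -> Cohort:
    """A cohort with the configured mechanism mix. A propensity track (and
    decoys) is generated when ``config.propensity_weight`` is nonzero or
    ``randomize_boundaries`` is set."""
    if mechanism_mix is None:
        mechanism_mix = {MECH_TB: 0.5, MECH_BFB: 0.25, MECH_CHROMOTHRIPSIS: 0.25}
    bad = set(mechanism_mix) - set(MECHANISMS)
    if bad:
        raise ValueError(f"unknown mechanisms in mix: {sorted(bad)}")
    total = sum(mechanism_mix.values())
    if not total > 0:
        raise ValueError("mechanism mix must have positive total probability")
    names = sorted(mechanism_mix)
    probs = np.array([mechanism_mix[m] / total for m in names])
    rng = np.random.default_rng(seed)
    layout = make_layout(config)
    track = None
    decoys: list[PropensityTrack] = []
    if config.propensity_weight != 0 or config.randomize_boundaries:
        track = make_propensity_track(config, layout, rng)
        decoys = make_decoy_tracks(track, config, rng)
    oncogenes = oncogene_positions(config, layout)
    samples = []
    for i in range(n_samples):
        mech = str(rng.choice(names, p=probs))
        samples.append(
            simulate_sample(
                config, layout, rng, f"S{i + 1:04d}", mech,
                track=track, oncogenes=oncogenes, with_snvs=with_snvs,
            )
        )
    return Cohort(config=config, layout=layout, samples=samples, track=track, decoys=decoys)


def simulate_clock_cohort(
    n_samples: int, seed: int, rate_per_year: float = 29.4,
    age_range: tuple[float, float] = (25.0, 80.0),
) -> tuple[list[SampleInfo], dict[str, float]]:
    """Manifest-level cohort for clock calibration: clonal SNV counts drawn
    Poisson(rate x age) for clock-eligible samples."""
    rng = np.random.default_rng(seed)
    manifest, burdens = [], {}
    for i in range(n_samples):
        sample = f"C{i + 1:04d}"
        age = float(rng.uniform(*age_range))
        count = int(rng.poisson(rate_per_year * age))
        manifest.append(
            SampleInfo(
                sample=sample, purity=float(rng.uniform(0.6, 0.95)), age=age,
                er_status=True, hr_deficient=False, wgd=False, msi=False,
                sbs2_13_fraction=float(rng.uniform(0, 0.4)), snv_count=count,
            )
        )
        burdens[sample] = float(count)
    return manifest, burdens


# ------------------------------------------------------------------- I/O

def truth_to_dict(cohort: Cohort) -> dict:
    out = {"samples": {}}
    for s in cohort.samples:
        out["samples"][s.sample] = {
            "events": [
                {**asdict(e), "bridge_arms": [list(a) for a in e.bridge_arms]}
                for e in s.events
            ],
            "sv_labels": s.sv_labels,
            "snv_labels": {
                f"{chrom}:{pos}": lab for (chrom, pos), lab in s.snv_labels.items()
            },
        }
    return out


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the pipeline's input formats plus a truth JSON."""
    from . import io as tio
    from .genome import write_genome_layout

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cytoband": outdir / "genome.cytoband.tsv",
        "segments": outdir / "segments.tsv",
        "svs": outdir / "svs.bedpe",
        "snvs": outdir / "snvs.tsv",
        "manifest": outdir / "manifest.tsv",
        "truth": outdir / "truth.json",
    }
    write_genome_layout(cohort.layout, paths["cytoband"])
    tio.write_cn_segments(cohort.segments, paths["segments"])
    tio.write_sv_bedpe(cohort.svs, paths["svs"])
    tio.write_snv_table(cohort.snvs, paths["snvs"])
    tio.write_manifest(cohort.manifest, paths["manifest"])
    if cohort.track is not None:
        paths["track"] = outdir / "propensity.bedgraph"
        tio.write_feature_track(cohort.track.to_feature_track(), paths["track"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth_to_dict(cohort), fh, indent=1)
    return paths
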