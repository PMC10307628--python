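"""Simulator invariants: dual-LOH theorem, conservation, determinism,
mechanism cross-consistency, and clock expectations."""

import numpy as np
import pytest

from tbamp import amplicons as amp_mod
from tbamp import boundaries as bnd_mod
from tbamp.boundaries import (
    CAT_DOUBLE_MINUTE,
    CAT_FOLD_BACK,
    CAT_TANDEM_DUPLICATION,
    amplified_sv_threshold,
)
from tbamp.sim import (
    MECH_BFB,
    MECH_CHROMOTHRIPSIS,
    MECH_SIMPLE_DM,
    MECH_TANDEM_DUP,
    MECH_TB,
    SimConfig,
    simulate_cohort,
    simulate_sample,
    truth_to_dict,
    write_cohort,
)
from tbamp.tb import telomeric_loh_fraction


def _classify_truth_amplicon(s, layout):
    baselines = amp_mod.arm_baselines(s.segments, layout)
    amps = amp_mod.call_amplicons(s.segments, baselines, layout)
    calls = bnd_mod.classify_boundaries(amps, s.svs)
    chrom, lo, hi = s.events[0].amplicons[0]
    for c in calls:
        if c.amplicon.chrom == chrom and c.amplicon.start < hi and c.amplicon.end > lo:
            return c.category
    return None


class TestTBFootprint:
    def test_dual_loh_theorem_holds_for_every_draw(self, layout):
        """The daughter inheriting two anti-parallel hemi-dicentrics always
        shows telomeric LOH on both bridge arms and none on non-bridge arms."""
        rng = np.random.default_rng(42)
        cfg = SimConfig()
        for i in range(60):
            s = simulate_sample(cfg, layout, rng, f"S{i}", MECH_TB, with_snvs=False)
            for chrom, arm in s.events[0].bridge_arms:
                assert telomeric_loh_fraction(s.segments, layout, chrom, arm) > 0
                other = "p" if arm == "q" else "q"
                assert telomeric_loh_fraction(s.segments, layout, chrom, other) == 0.0

    def test_allele_cn_always_consistent(self, layout, rng):
        for i, mech in enumerate([MECH_TB, MECH_BFB, MECH_CHROMOTHRIPSIS]):
            s = simulate_sample(SimConfig(), layout, rng, f"S{i}", mech, with_snvs=False)
            for seg in s.segments:
                assert seg.cn_total == pytest.approx(seg.cn_major + seg.cn_minor)
                assert seg.cn_major >= seg.cn_minor >= 0

    def test_segments_tile_each_chromosome(self, layout, rng):
        s = simulate_sample(SimConfig(), layout, rng, "S1", MECH_TB, with_snvs=False)
        by_chrom = {}
        for seg in s.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda x: x.start)
            assert segs[0].start == 0 and segs[-1].end == layout.length(chrom)
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start

    def test_boundary_support_dominates_background(self, layout):
        """When the ecDNA copy number is >= 20 the boundary-SV support is at
        least five times the background median, and the inflection-based
        threshold captures the boundary SVs."""
        rng = np.random.default_rng(11)
        cfg = SimConfig(ecdna_cn_range=(20.0, 100.0))
        captured = 0
        n = 20
        for i in range(n):
            s = simulate_sample(cfg, layout, rng, f"S{i}", MECH_TB, with_snvs=False)
            boundary = [sv for sv in s.svs if s.sv_labels[sv.id] == "tb_boundary"]
            background = [sv.support for sv in s.svs
                          if s.sv_labels[sv.id] != "tb_boundary"]
            assert min(b.support for b in boundary) >= 5 * np.median(background)
            thr = amplified_sv_threshold(s.svs)
            captured += all(b.id in thr.amplified_ids for b in boundary)
        assert captured >= 0.9 * n


class TestDeterminism:
    def test_same_seed_same_cohort(self, tmp_path):
        cfg = SimConfig()
        a = simulate_cohort(cfg, seed=5, n_samples=4, with_snvs=True)
        b = simulate_cohort(cfg, seed=5, n_samples=4, with_snvs=True)
        assert truth_to_dict(a) == truth_to_dict(b)
        pa = write_cohort(a, tmp_path / "a")
        pb = write_cohort(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_text() == pb[key].read_text()

    def test_different_seed_differs(self):
        cfg = SimConfig()
        a = simulate_cohort(cfg, seed=5, n_samples=2)
        b = simulate_cohort(cfg, seed=6, n_samples=2)
        assert truth_to_dict(a) != truth_to_dict(b)


class TestMechanisms:
    def test_bfb_stair_step_is_monotone_toward_amplicon(self, layout, rng):
        for i in range(10):
            s = simulate_sample(SimConfig(), layout, rng, f"S{i}", MECH_BFB,
                                with_snvs=False)
            chrom, lo, hi = s.events[0].amplicons[0]
            arm = layout.arm(chrom, "q")
            steps = sorted(
                (seg for seg in s.segments
                 if seg.chrom == chrom and arm.start <= seg.start and seg.end <= hi),
                key=lambda x: x.start,
            )
            cns = [seg.cn_total for seg in steps]
            assert all(b >= a - 0.5 for a, b in zip(cns, cns[1:]))
            # LOH only on the event arm; all other chromosomes untouched
            for other in layout.chromosomes:
                if other != chrom:
                    assert telomeric_loh_fraction(s.segments, layout, other, "q") == 0.0

    @pytest.mark.parametrize(
        "mechanism,expected",
        [
            (MECH_BFB, CAT_FOLD_BACK),
            (MECH_SIMPLE_DM, CAT_DOUBLE_MINUTE),
            (MECH_TANDEM_DUP, CAT_TANDEM_DUPLICATION),
        ],
    )
    def test_boundary_module_recovers_mechanism(self, layout, mechanism, expected):
        rng = np.random.default_rng(hash(mechanism) % 2**31)
        hits = 0
        for i in range(15):
            s = simulate_sample(SimConfig(), layout, rng, f"S{i}", mechanism,
                                with_snvs=False)
            hits += _classify_truth_amplicon(s, layout) == expected
        assert hits >= 14

    def test_unknown_mechanism_rejected(self, layout, rng):
        from tbamp.sim import _Builder, simulate_other

        b = _Builder("S1", SimConfig(), layout, rng, None)
        with pytest.raises(ValueError):
            simulate_other(b, 50.0, "spaghettification", "1")


class TestCohort:
    def test_mechanism_mix_realized_within_tolerance(self):
        mix = {MECH_TB: 0.5, MECH_BFB: 0.25, MECH_CHROMOTHRIPSIS: 0.25}
        cohort = simulate_cohort(SimConfig(), seed=2, n_samples=100,
                                 mechanism_mix=mix)
        got = {m: 0 for m in mix}
        for s in cohort.samples:
            got[s.events[0].mechanism] += 1
        for m, p in mix.items():
            assert got[m] / 100 == pytest.approx(p, abs=0.1)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(), 1, 5, mechanism_mix={"warp_drive": 1.0})
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(), 1, 5, mechanism_mix={MECH_TB: 0.0})

    def test_zero_weight_track_uncorrelated_with_breakpoints(self):
        cfg = SimConfig(propensity_weight=0.0, randomize_boundaries=True)
        cohort = simulate_cohort(cfg, seed=9, n_samples=60,
                                 mechanism_mix={MECH_TB: 1.0})
        track = cohort.track
        scores, counts = [], {}
        for s in cohort.samples:
            for sv in s.svs:
                for be in (sv.breakend1, sv.breakend2):
                    key = (be.chrom, be.pos // track.bin_bp)
                    counts[key] = counts.get(key, 0) + 1
        per_bin = []
        for chrom, arr in track.scores.items():
            for i, sc in enumerate(arr):
                per_bin.append((sc, counts.get((chrom, i), 0)))
        arr = np.array(per_bin)
        r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
        assert abs(r) < 0.1


class TestSNVClock:
    def test_pre_event_count_matches_poisson_expectation(self, layout):
        """Expected pre-gain SNV count on a gained arm ~ (rate/2) x age x length."""
        cfg = SimConfig(event_age=40.0, gain_delay_years=(0.0, 0.0),
                        age_mean=60.0, age_sd=0.1, non_bridge_gain_prob=1.0)
        rng = np.random.default_rng(21)
        totals, expect = 0, 0.0
        for i in range(30):
            s = simulate_sample(cfg, layout, rng, f"S{i}", MECH_TB,
                                force_non_bridge_gain=True, with_snvs=True)
            for chrom, _ in s.events[0].bridge_arms:
                hi = layout.centromere(chrom)[0]
                expect += cfg.clock_rate_per_mb_yr / 2 * 40.0 * hi / 1e6
                totals += sum(
                    1 for (c, pos), lab in s.snv_labels.items()
                    if c == chrom and pos <= hi and lab["label"] == "pre_gain"
                )
        sigma = np.sqrt(expect)
        assert abs(totals - expect) <= 3.5 * sigma

    def test_pre_event_vaf_expectation(self, layout):
        """Pre-gain mutations on K amplified copies have expected VAF
        K x purity / (purity x cn_total + 2(1 - purity))."""
        cfg = SimConfig(purity=1.0)
        rng = np.random.default_rng(33)
        vafs, expected = [], []
        for i in range(50):
            s = simulate_sample(cfg, layout, rng, f"S{i}", MECH_TB, with_snvs=True)
            for rec in s.snvs:
                lab = s.snv_labels[(rec.chrom, rec.pos)]
                if lab["label"] == "pre_gain" and lab["multiplicity"] >= 5:
                    vafs.append(rec.vaf)
                    expected.append(lab["multiplicity"] / lab["cn_total"])
        assert len(vafs) > 5
        assert np.mean(np.array(vafs) - np.array(expected)) == pytest.approx(0, abs=0.05)
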