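"""SV clustering, TB-footprint detection, rounds, and the association screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from tbamp import amplicons as amp_mod
from tbamp import boundaries as bnd_mod
from tbamp.records import Breakend, SVRecord
from tbamp.sim import SimConfig, simulate_sample
from tbamp.tb import (
    cluster_svs,
    cohort_association,
    detect_tb_events,
    flag_extensive,
    partition_rounds,
    telomeric_loh_fraction,
)

MB = 1_000_000


def sv(c1, p1, o1, c2, p2, o2, support=10, id="sv", sample="S1"):
    return SVRecord(sample=sample, breakend1=Breakend(c1, p1, o1),
                    breakend2=Breakend(c2, p2, o2), support=support, id=id)


def _run_sample(s, layout):
    baselines = amp_mod.arm_baselines(s.segments, layout)
    amps = amp_mod.call_amplicons(s.segments, baselines, layout)
    calls = bnd_mod.classify_boundaries(amps, s.svs)
    clusters = cluster_svs(s.svs, layout)
    return detect_tb_events(clusters, calls, s.segments, layout, baselines=baselines)


class TestClustering:
    def test_translocations_sharing_arm_pair_merge(self, layout):
        qa = layout.arm("1", "q").start + 5 * MB
        qb = layout.arm("2", "q").start + 5 * MB
        t1 = sv("1", qa, "L", "2", qb, "L", id="t1")
        t2 = sv("1", qa + 40 * MB, "R", "2", qb + 30 * MB, "R", id="t2")
        clusters = cluster_svs([t1, t2], layout, proximity_bp=5 * MB)
        assert len(clusters) == 1 and clusters[0].n_sv == 2

    def test_distant_intrachromosomal_svs_stay_apart(self, layout):
        a = sv("1", 10 * MB, "L", "1", 11 * MB, "R", id="a")
        b = sv("1", 30 * MB, "L", "1", 31 * MB, "R", id="b")
        clusters = cluster_svs([a, b], layout, proximity_bp=5 * MB)
        assert len(clusters) == 2

    def test_components_equal_pairwise_closure_oracle(self, layout, rng):
        """Union-find output equals the transitive closure of the pairwise
        merge rules computed by brute force."""
        chroms = layout.chromosomes[:4]
        for _ in range(30):
            svs = []
            for i in range(rng.integers(5, 15)):
                if rng.random() < 0.5:
                    c = str(rng.choice(chroms))
                    p1 = int(rng.integers(MB, layout.length(c) - MB))
                    p2 = min(p1 + int(rng.integers(1000, 30 * MB)), layout.length(c) - 1)
                    o = str(rng.choice(["L", "R"]))
                    o2 = o if rng.random() < 0.3 and p2 - p1 < 5000 else str(rng.choice(["L", "R"]))
                    svs.append(sv(c, p1, o, c, p2, o2, id=f"s{i}"))
                else:
                    c1, c2 = (str(x) for x in rng.choice(chroms, size=2, replace=False))
                    svs.append(sv(c1, int(rng.integers(MB, layout.length(c1) - MB)), "L",
                                  c2, int(rng.integers(MB, layout.length(c2) - MB)), "R",
                                  id=f"s{i}"))
            prox = 5 * MB

            def linked(x, y):
                for bx in (x.breakend1, x.breakend2):
                    for by in (y.breakend1, y.breakend2):
                        if bx.chrom == by.chrom and abs(bx.pos - by.pos) <= prox:
                            return True
                def armpair(s):
                    return tuple(sorted(
                        (b.chrom, layout.arm_of(b.chrom, b.pos))
                        for b in (s.breakend1, s.breakend2)))
                if x.is_translocation and y.is_translocation and armpair(x) == armpair(y):
                    return True
                if x.is_foldback and y.is_foldback:
                    ax = (x.breakend1.chrom, layout.arm_of(x.breakend1.chrom, x.breakend1.pos))
                    ay = (y.breakend1.chrom, layout.arm_of(y.breakend1.chrom, y.breakend1.pos))
                    if ax == ay:
                        return True
                return False

            # brute-force closure
            groups = {s.id: {s.id} for s in svs}
            changed = True
            while changed:
                changed = False
                for x, y in itertools.combinations(svs, 2):
                    if linked(x, y) and groups[x.id] is not groups[y.id]:
                        merged = groups[x.id] | groups[y.id]
                        for m in merged:
                            groups[m] = merged
                        changed = True
            oracle = {frozenset(g) for g in groups.values()}
            got = {frozenset(s.id for s in c.svs) for c in cluster_svs(svs, layout, prox)}
            assert got == oracle


class TestDetection:
    def test_simulated_tb_event_recovered_with_dual_loh(self, layout, rng):
        s = simulate_sample(SimConfig(), layout, rng, "S1", "TB", with_snvs=False)
        events = _run_sample(s, layout)
        assert len(events) >= 1
        ev = events[0]
        true_arms = {tuple(a) for a in s.events[0].bridge_arms}
        assert true_arms <= set(ev.bridge_arms)
        assert ev.dual_loh
        assert all(ev.loh_fractions[a] > 0 for a in true_arms)

    def test_small_clusters_are_not_reported(self, layout):
        qa = layout.arm("1", "q").start
        svs = [sv("1", qa + i * MB, "L", "2", layout.arm("2", "q").start + i * MB, "L",
                  id=f"t{i}") for i in range(9)]
        clusters = cluster_svs(svs, layout)
        assert max(c.n_sv for c in clusters) == 9
        events = detect_tb_events(clusters, [], [], layout, baselines={})
        assert events == []

    def test_chromothripsis_on_one_chromosome_is_not_tb(self, layout, rng):
        s = simulate_sample(SimConfig(), layout, rng, "S1", "chromothripsis",
                            with_snvs=False)
        assert _run_sample(s, layout) == []

    def test_bfb_is_not_tb(self, layout, rng):
        s = simulate_sample(SimConfig(), layout, rng, "S1", "BFB", with_snvs=False)
        assert _run_sample(s, layout) == []

    def test_non_bridge_arms_retain_heterozygosity(self, layout, rng):
        """Emitted TB daughters keep minor CN >= 1 on both non-bridge (p)
        arms while both bridge arms end in telomeric LOH."""
        for i in range(20):
            s = simulate_sample(SimConfig(), layout, rng, f"S{i}", "TB", with_snvs=False)
            for chrom, arm in s.events[0].bridge_arms:
                assert telomeric_loh_fraction(s.segments, layout, chrom, arm) > 0
                p_arm = layout.arm(chrom, "p")
                for seg in s.segments:
                    if seg.chrom == chrom and seg.end <= p_arm.end:
                        assert round(seg.cn_minor) >= 1


class TestExtensive:
    def _event(self, n_translocations, layout):
        qa = layout.arm("1", "q").start
        qb = layout.arm("2", "q").start
        svs = [sv("1", qa + i * MB, "L", "2", qb + i * MB, "L", id=f"t{i}")
               for i in range(n_translocations)]
        from tbamp.tb import SVCluster, TBEvent
        cluster = SVCluster(sample="S1", svs=svs)
        return TBEvent(cluster=cluster, bridge_arms=[("1", "q"), ("2", "q")],
                       loh_fractions={}, dual_loh=True, non_bridge_sv_counts={})

    def test_ten_or_more_translocations_is_extensive(self, layout):
        assert flag_extensive(self._event(12, layout))
        assert not flag_extensive(self._event(9, layout))

    def test_extensive_preset_always_flags(self, layout, rng):
        for i in range(10):
            s = simulate_sample(SimConfig(), layout, rng, f"S{i}", "TB",
                                extensive=True, with_snvs=False)
            events = _run_sample(s, layout)
            assert events and events[0].extensive


class TestRounds:
    def test_disjoint_translocation_bundles_are_two_rounds(self, layout):
        from tbamp.tb import SVCluster, TBEvent

        def mk(c1, c2, tag):
            qa, qb = layout.arm(c1, "q").start, layout.arm(c2, "q").start
            svs = [sv(c1, qa + i * MB, "L", c2, qb + i * MB, "L", id=f"{tag}{i}")
                   for i in range(3)]
            return TBEvent(cluster=SVCluster("S1", svs), bridge_arms=[(c1, "q")],
                           loh_fractions={}, dual_loh=True, non_bridge_sv_counts={})

        a, b = mk("1", "2", "a"), mk("3", "4", "b")
        partition_rounds([a, b])
        assert a.round_id != b.round_id
        c, d = mk("1", "2", "c"), mk("2", "5", "d")
        partition_rounds([c, d])
        assert c.round_id == d.round_id

    def test_rounds_equal_connected_components_oracle(self, layout, rng):
        import networkx as nx
        from tbamp.tb import SVCluster, TBEvent

        chroms = layout.chromosomes
        for _ in range(20):
            events = []
            for e in range(rng.integers(1, 5)):
                c1, c2 = (str(x) for x in rng.choice(chroms, size=2, replace=False))
                svs = [sv(c1, layout.arm(c1, "q").start + MB, "L",
                          c2, layout.arm(c2, "q").start + MB, "L", id=f"e{e}")]
                events.append(TBEvent(cluster=SVCluster("S1", svs),
                                      bridge_arms=[(c1, "q")], loh_fractions={},
                                      dual_loh=True, non_bridge_sv_counts={}))
            partition_rounds(events)
            g = nx.Graph()
            for ev in events:
                g.add_edge(*sorted(ev.cluster.chromosomes))
            comps = list(nx.connected_components(g))

            def comp_of(ev):
                ch = next(iter(ev.cluster.chromosomes))
                return next(i for i, c in enumerate(comps) if ch in c)

            for x, y in itertools.combinations(events, 2):
                same_round = x.round_id == y.round_id
                assert same_round == (comp_of(x) == comp_of(y))


class TestAssociation:
    def test_fisher_matches_hypergeometric_oracle(self):
        samples = [f"P{i}" for i in range(100)]
        tb = pd.Series([i < 50 for i in range(100)], index=samples)
        altered = [i < 10 or (50 <= i < 90) for i in range(100)]  # 10/50 vs 40/50
        table = pd.DataFrame({"GENE": altered}, index=samples)
        res = cohort_association(table, tb, min_frequency=0.0, top_fraction=1.0)
        a, b, c, d = 10, 40, 40, 10
        n, K, N = a + b + c + d, a + b, a + c
        support = np.arange(max(0, K + N - n), min(K, N) + 1)
        pmf = hypergeom.pmf(support, n, K, N)
        p_oracle = float(pmf[pmf <= pmf[support == a][0] * (1 + 1e-9)].sum())
        assert res.loc[0, "p"] == pytest.approx(p_oracle, rel=1e-9)
        assert res.loc[0, "odds_ratio"] == pytest.approx((a * d) / (b * c), rel=1e-9)

    def test_rare_genes_excluded(self):
        samples = [f"P{i}" for i in range(100)]
        tb = pd.Series([i % 2 == 0 for i in range(100)], index=samples)
        table = pd.DataFrame(
            {"RARE": [i < 4 for i in range(100)],
             "COMMON": [i < 50 for i in range(100)]},
            index=samples,
        )
        res = cohort_association(table, tb, top_fraction=1.0)
        assert set(res["gene"]) == {"COMMON"}

    def test_degenerate_table_uses_haldane_and_flags(self):
        samples = [f"P{i}" for i in range(40)]
        tb = pd.Series([i < 20 for i in range(40)], index=samples)
        table = pd.DataFrame({"G": [i < 20 for i in range(40)]}, index=samples)
        res = cohort_association(table, tb, top_fraction=1.0, min_frequency=0.0)
        assert bool(res.loc[0, "haldane"])
        assert np.isfinite(res.loc[0, "odds_ratio"])

    def test_permutation_null_controls_fdr(self, rng):
        """Label-permuted inputs: expected fraction of q<0.1 hits stays low."""
        samples = [f"P{i}" for i in range(80)]
        table = pd.DataFrame(
            {f"G{j}": rng.random(80) < 0.3 for j in range(20)}, index=samples
        )
        hits = 0
        tests = 0
        for _ in range(50):
            tb = pd.Series(rng.permutation([True] * 30 + [False] * 50), index=samples)
            res = cohort_association(table, tb, top_fraction=1.0, min_frequency=0.0)
            hits += int(res["significant"].sum())
            tests += len(res)
        assert hits / tests <= 0.1
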