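"""Bin-level enrichment: Fisher overlap, LASSO, ratios, GSEA, ER score."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from tbamp.enrichment import (
    bin_genome,
    breakpoint_ratio,
    count_positions,
    derive_responsive_genes,
    er_activity_score,
    gene_ranked_enrichment,
    lasso_model,
    overlap_fisher,
    track_bin_values,
)
from tbamp.genome import GenomeLayout

MB = 1_000_000


class TestBins:
    def test_even_tiling(self):
        layout = GenomeLayout(lengths={"1": 10 * MB}, centromeres={"1": (4 * MB, 5 * MB)})
        bins = bin_genome(layout, 100_000)
        assert len(bins) == 100
        assert all(b.end - b.start == 100_000 for b in bins)

    def test_truncated_terminal_bin(self):
        layout = GenomeLayout(lengths={"1": 10_050_000}, centromeres={"1": (4 * MB, 5 * MB)})
        bins = bin_genome(layout, 100_000)
        assert len(bins) == 101
        assert bins[-1].end - bins[-1].start == 50_000

    def test_binned_length_conserved(self, layout):
        bins = bin_genome(layout, 250_000)
        assert sum(b.end - b.start for b in bins) == layout.total_length

    def test_position_counting(self, toy_layout):
        bins = bin_genome(toy_layout, MB)
        counts = count_positions(bins, [("1", 0), ("1", 999_999), ("1", MB), ("2", 5)])
        assert counts[0] == 2 and counts[1] == 1
        assert counts[100] == 1  # first bin of chromosome 2


class TestFisher:
    def test_matches_hypergeometric_enumeration(self):
        # 2x2 = [[30, 70], [10, 190]]
        peak = np.array([True] * 100 + [False] * 200)
        target = np.array([True] * 30 + [False] * 70 + [True] * 10 + [False] * 190)
        res = overlap_fisher(peak, target)
        n, K, N, a = 300, 100, 40, 30
        support = np.arange(max(0, K + N - n), min(K, N) + 1)
        p_oracle = float(hypergeom.pmf(support, n, K, N)[support >= a].sum())
        assert res.p == pytest.approx(p_oracle, rel=1e-9)
        assert res.odds_ratio == pytest.approx((30 * 190) / (70 * 10), rel=1e-9)

    def test_null_p_values_roughly_uniform(self, rng):
        pvals = []
        for _ in range(200):
            peak = rng.random(200) < 0.3
            target = rng.random(200) < 0.2
            pvals.append(overlap_fisher(peak, target).p)
        # discrete test: conservative, so compare against stochastic dominance
        assert kstest(pvals, "uniform").statistic < 0.25
        assert np.mean(np.array(pvals) < 0.05) < 0.1

    def test_degenerate_table_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = overlap_fisher(np.ones(50, dtype=bool), np.arange(50) < 10)
        assert res.degenerate and np.isfinite(res.odds_ratio)


class TestLasso:
    def test_planted_feature_recovered(self, rng):
        n = 2000
        base = rng.normal(size=n)
        feats = {"f1": base}
        for i in range(5):  # correlated decoys
            feats[f"d{i}"] = 0.6 * base + 0.8 * rng.normal(size=n)
        X = pd.DataFrame(feats)
        y = 3.0 * X["f1"].to_numpy() + rng.normal(size=n)
        m = lasso_model(y, X, n_permutations=100, seed=0)
        assert m.ranked_features()[0] == "f1"
        assert m.permutation_p["f1"] < 0.05

    def test_pure_noise_rarely_significant(self, rng):
        clean = 0
        for r in range(30):
            X = pd.DataFrame({f"f{i}": rng.normal(size=300) for i in range(4)})
            y = rng.normal(size=300)
            m = lasso_model(y, X, n_permutations=60, seed=r)
            clean += not any(p < 0.05 for p in m.permutation_p.values())
        assert clean >= 27  # >= 90% of replicates

    def test_identical_features_have_extreme_vif(self, rng):
        base = rng.normal(size=500)
        X = pd.DataFrame({"a": base, "b": base.copy(), "c": rng.normal(size=500)})
        m = lasso_model(rng.normal(size=500), X, n_permutations=10, seed=0)
        assert m.vif["a"] > 10 and m.vif["b"] > 10
        assert m.vif["c"] < 5

    def test_constant_feature_dropped_with_warning(self, rng):
        X = pd.DataFrame({"flat": np.ones(100), "ok": rng.normal(size=100)})
        with pytest.warns(UserWarning, match="constant"):
            m = lasso_model(rng.normal(size=100), X, n_permutations=10, seed=0)
        assert m.dropped == ["flat"] and m.features == ["ok"]

    def test_single_feature_no_penalty_limit_matches_ols(self, rng):
        x = rng.normal(size=1000)
        y = 2.5 * x + rng.normal(size=1000)
        X = pd.DataFrame({"x": x})
        m = lasso_model(y, X, n_permutations=2, seed=0, alphas=[1e-10])
        xs = (x - x.mean()) / x.std()
        beta_ols = float(np.dot(xs, y - y.mean()) / np.dot(xs, xs))
        assert m.coefficients["x"] == pytest.approx(beta_ols, abs=1e-6)


class TestRatio:
    def _bins(self, toy_layout):
        return bin_genome(toy_layout, MB)

    def test_fourfold_rule_is_strict(self, toy_layout):
        bins = self._bins(toy_layout)
        control = np.zeros(len(bins))
        treated = np.zeros(len(bins))
        control[0], treated[0] = 4, 20    # (20+1)/(4+1) = 4.2 -> hotspot
        control[1], treated[1] = 1, 4     # (4+1)/(1+1) = 2.5 -> not
        res = breakpoint_ratio(bins, control, treated)
        assert res.ratios[0] == pytest.approx(4.2)
        assert bool(res.hotspot[0]) and not bool(res.hotspot[1])

    def test_bait_region_never_hotspot(self, toy_layout):
        bins = self._bins(toy_layout)
        treated = np.full(len(bins), 1000.0)
        control = np.zeros(len(bins))
        res = breakpoint_ratio(bins, control, treated, bait=("1", 50 * MB, 51 * MB))
        for i, b in enumerate(bins):
            inside = b.chrom == "1" and b.start < 52 * MB and b.end > 49 * MB
            assert bool(res.masked[i]) == inside
            if inside:
                assert not res.hotspot[i]

    def test_reciprocal_symmetry_without_pseudocount(self, toy_layout, rng):
        bins = self._bins(toy_layout)
        control = rng.integers(1, 50, size=len(bins)).astype(float)
        treated = rng.integers(1, 50, size=len(bins)).astype(float)
        fwd = breakpoint_ratio(bins, control, treated, pseudocount=0.0)
        rev = breakpoint_ratio(bins, treated, control, pseudocount=0.0)
        assert np.allclose(fwd.ratios, 1.0 / rev.ratios)


class TestGSEA:
    def test_top_ranked_set_is_enriched(self):
        scores = pd.Series(np.linspace(5, -5, 1000), index=[f"g{i}" for i in range(1000)])
        res = gene_ranked_enrichment(scores, [f"g{i}" for i in range(10)],
                                     n_permutations=500, seed=0)
        assert res.es > 0
        assert res.p < 0.01

    def test_random_set_p_uniform(self, rng):
        scores = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
        pvals = []
        for r in range(100):
            members = rng.choice(scores.index, size=50, replace=False)
            pvals.append(gene_ranked_enrichment(scores, list(members),
                                                n_permutations=100, seed=r).p)
        assert kstest(pvals, "uniform").statistic < 0.2

    def test_set_equal_to_universe_is_degenerate(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        res = gene_ranked_enrichment(scores, ["a", "b", "c"], n_permutations=10, seed=0)
        assert res.p == 1.0

    def test_empty_intersection_is_an_error(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            gene_ranked_enrichment(scores, ["zzz"], n_permutations=10, seed=0)


class TestERScore:
    def _matrix(self, rng, n_genes=40, n_samples=30):
        return pd.DataFrame(
            rng.normal(5, 1, size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_sample_above_all_medians_scores_one(self, rng):
        expr = self._matrix(rng)
        expr["top"] = expr.max(axis=1) + 1
        scores = er_activity_score(expr, list(expr.index))
        assert scores["top"] == 1.0

    def test_median_is_inclusive(self, rng):
        expr = self._matrix(rng, n_samples=9)
        expr["mid"] = expr.median(axis=1)
        scores = er_activity_score(expr, list(expr.index))
        assert scores["mid"] == 1.0  # "50th percentile or higher" includes equality

    def test_planted_upregulated_subset_recovered(self, rng):
        n_pos, n_neg = 100, 100
        genes = [f"g{i}" for i in range(60)]
        planted = set(genes[:25])
        cols = [f"pos{i}" for i in range(n_pos)] + [f"neg{i}" for i in range(n_neg)]
        data = rng.normal(5, 1, size=(60, n_pos + n_neg))
        for gi, g in enumerate(genes):
            if g in planted:
                data[gi, :n_pos] += 2.0
        expr = pd.DataFrame(data, index=genes, columns=cols)
        derived = derive_responsive_genes(
            expr, genes, [c for c in cols if c.startswith("pos")],
            [c for c in cols if c.startswith("neg")],
        )
        jaccard = len(planted & set(derived)) / len(planted | set(derived))
        assert jaccard >= 0.9

    def test_too_few_samples_per_group_is_an_error(self, rng):
        expr = self._matrix(rng, n_samples=4)
        with pytest.raises(ValueError):
            derive_responsive_genes(expr, list(expr.index), ["s0"], ["s1", "s2"])


def test_track_bin_values_binary_and_mean(toy_layout):
    from tbamp.records import FeatureInterval, FeatureTrack

    bins = bin_genome(toy_layout, MB)
    peaks = FeatureTrack("peaks", [FeatureInterval("1", 500_000, 1_500_000, 1.0)])
    v = track_bin_values(bins, peaks)
    assert v[0] == 1.0 and v[1] == 1.0 and v[2] == 0.0
    signal = FeatureTrack("sig", [FeatureInterval("1", 0, MB, 2.0),
                                  FeatureInterval("1", MB, 2 * MB, 4.0)])
    v = track_bin_values(bins, signal)
    assert v[0] == pytest.approx(2.0) and v[1] == pytest.approx(4.0)
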