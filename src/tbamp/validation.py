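"""Validation experiments: the simulator-vs-pipeline recovery studies.

Each function runs one self-contained experiment — simulate under the
default study conditions, run the relevant pipeline stage from scratch,
and measure recovery against the generative truth. The test suite asserts
on these numbers and the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import amplicons as amp_mod
from . import boundaries as bnd_mod
from . import tb as tb_mod
from .boundaries import (
    CAT_DOUBLE_MINUTE,
    CAT_FOLD_BACK,
    CAT_TANDEM_DUPLICATION,
    CAT_TRANSLOCATION,
)
from .enrichment import bin_genome, count_positions, lasso_model
from .sim import (
    MECH_BFB,
    MECH_CHROMOTHRIPSIS,
    MECH_SIMPLE_DM,
    MECH_TANDEM_DUP,
    MECH_TB,
    SimConfig,
    make_layout,
    simulate_clock_cohort,
    simulate_cohort,
    simulate_sample,
)
from .timing import (
    LABEL_PRE,
    ancestral_burden,
    burden_to_age,
    classify_snv_timing,
    estimate_clock_rate,
)

EXPECTED_CATEGORY = {
    MECH_TB: CAT_TRANSLOCATION,
    MECH_BFB: CAT_FOLD_BACK,
    MECH_SIMPLE_DM: CAT_DOUBLE_MINUTE,
    MECH_TANDEM_DUP: CAT_TANDEM_DUPLICATION,
}


def worked_example_years(
    burden_per_mb: float = 0.52, genome_mb: float = 2_880.0, rate: float = 29.4
) -> float:
    """Median non-bridge-arm gain timing implied by a 0.52/Mb ancestral
    burden under the 29.4 SNVs/yr clonal clock (~51 years)."""
    return burden_to_age(burden_per_mb, genome_mb, rate)


def _classify_sample(s, layout):
    baselines = amp_mod.arm_baselines(s.segments, layout)
    amps = amp_mod.call_amplicons(s.segments, baselines, layout)
    calls = bnd_mod.classify_boundaries(amps, s.svs)
    return baselines, calls


def mechanism_recovery(seed: int, n_per_mechanism: int = 50) -> dict:
    """Amplicon-level boundary category vs generative mechanism on TB, BFB,
    double-minute and tandem-duplication events at default noise."""
    config = SimConfig()
    layout = make_layout(config)
    rng = np.random.default_rng(seed)
    correct = total = 0
    for mech, expected in EXPECTED_CATEGORY.items():
        for i in range(n_per_mechanism):
            s = simulate_sample(config, layout, rng, f"{mech}{i}", mech, with_snvs=False)
            _, calls = _classify_sample(s, layout)
            chrom, lo, hi = s.events[0].amplicons[0]
            got = next(
                (c.category for c in calls
                 if c.amplicon.chrom == chrom and c.amplicon.start < hi
                 and c.amplicon.end > lo),
                None,
            )
            correct += got == expected
            total += 1
    return {"accuracy": correct / total, "n": total}


def tb_detection(seed: int, n_per_group: int = 50) -> dict:
    """Sample-level TB-footprint detection: sensitivity on TB samples,
    specificity on chromothripsis-only and BFB-only samples."""
    config = SimConfig()
    layout = make_layout(config)
    rng = np.random.default_rng(seed)
    calls = {MECH_TB: [], MECH_CHROMOTHRIPSIS: [], MECH_BFB: []}
    for mech in calls:
        for i in range(n_per_group):
            s = simulate_sample(config, layout, rng, f"{mech}{i}", mech, with_snvs=False)
            baselines, classifications = _classify_sample(s, layout)
            clusters = tb_mod.cluster_svs(s.svs, layout)
            events = tb_mod.detect_tb_events(
                clusters, classifications, s.segments, layout, baselines=baselines
            )
            calls[mech].append(len(events) > 0)
    sensitivity = float(np.mean(calls[MECH_TB]))
    negatives = calls[MECH_CHROMOTHRIPSIS] + calls[MECH_BFB]
    specificity = 1.0 - float(np.mean(negatives))
    return {"sensitivity": sensitivity, "specificity": specificity,
            "n": 3 * n_per_group}


def dual_loh_stats(seed: int, n_draws: int = 500) -> dict:
    """The dual-LOH theorem over repeated TB draws: telomeric LOH on both
    bridge arms, none on non-bridge arms, and the mean LOH fraction under
    uniform bridge breakpoints."""
    config = SimConfig()
    layout = make_layout(config)
    rng = np.random.default_rng(seed)
    dual = clean_non_bridge = 0
    fractions = []
    for i in range(n_draws):
        s = simulate_sample(config, layout, rng, f"D{i}", MECH_TB, with_snvs=False)
        bridge = [tuple(a) for a in s.events[0].bridge_arms]
        fr = [
            tb_mod.telomeric_loh_fraction(s.segments, layout, c, a) for c, a in bridge
        ]
        fractions.extend(fr)
        dual += all(f > 0 for f in fr)
        clean_non_bridge += all(
            tb_mod.telomeric_loh_fraction(s.segments, layout, c, "p") == 0.0
            for c, _ in bridge
        )
    return {
        "dual_loh_fraction": dual / n_draws,
        "non_bridge_spared_fraction": clean_non_bridge / n_draws,
        "mean_bridge_loh_fraction": float(np.mean(fractions)),
        "n": n_draws,
    }


def clock_recovery(seed: int, n_samples: int = 150, rate: float = 29.4) -> dict:
    """Clonal clock calibration: generate an age-annotated cohort at a known
    rate and refit."""
    manifest, burdens = simulate_clock_cohort(n_samples, seed, rate_per_year=rate)
    model = estimate_clock_rate(manifest, burdens)
    return {
        "true_rate": rate,
        "estimated_rate": model.rate_per_year,
        "relative_error": abs(model.rate_per_year - rate) / rate,
        "n": len(model.eligible_samples),
    }


def _gained_arm_snvs(s, layout):
    for chrom, _ in s.events[0].bridge_arms:
        hi = layout.centromere(chrom)[0]  # gained non-bridge (p) arm
        for v in s.snvs:
            if v.chrom == chrom and 0 < v.pos <= hi:
                yield v, s.snv_labels[(v.chrom, v.pos)], hi


def label_accuracy(seed: int, n_target: int = 5_000) -> dict:
    """Pre-vs-post (amplified vs unamplified) classification accuracy at
    depth 60 on gained non-bridge arms."""
    config = SimConfig(non_bridge_gain_prob=1.0)
    layout = make_layout(config)
    rng = np.random.default_rng(seed)
    correct = total = 0
    i = 0
    while total < n_target:
        s = simulate_sample(config, layout, rng, f"L{i}", MECH_TB,
                            force_non_bridge_gain=True, with_snvs=True)
        i += 1
        for v, truth, _ in _gained_arm_snvs(s, layout):
            call = classify_snv_timing(v, 2, 1, config.purity)
            predicted_pre = call.label == LABEL_PRE
            truly_pre = truth["multiplicity"] >= 2
            correct += predicted_pre == truly_pre
            total += 1
    return {"accuracy": correct / total, "n": total}


def age_recovery(seed: int, true_ages=(30.0, 45.0, 60.0), n_replicates: int = 50) -> dict:
    """End-to-end gain timing: simulate TB with non-bridge gains at a known
    age, classify SNVs, convert ancestral burden back to years."""
    rng = np.random.default_rng(seed)
    out = {}
    for t in true_ages:
        config = SimConfig(
            event_age=float(t), gain_delay_years=(0.0, 0.0),
            age_mean=float(t) + 15.0, age_sd=2.0, non_bridge_gain_prob=1.0,
        )
        layout = make_layout(config)
        genome_mb = layout.total_length / 1e6
        rate = config.clock_rate_per_mb_yr * genome_mb
        estimates = []
        for i in range(n_replicates):
            s = simulate_sample(config, layout, rng, f"A{t}_{i}", MECH_TB,
                                force_non_bridge_gain=True, with_snvs=True)
            labels, lengths = [], []
            seen_arms = set()
            for v, _, hi in _gained_arm_snvs(s, layout):
                labels.append(classify_snv_timing(v, 2, 1, config.purity).label)
                if (v.chrom, hi) not in seen_arms:
                    seen_arms.add((v.chrom, hi))
                    lengths.append(hi)
            est = ancestral_burden(labels, lengths, n_bootstrap=50, rng=rng)
            estimates.append(burden_to_age(est.burden_per_mb, genome_mb, rate))
        median = float(np.median(estimates))
        out[float(t)] = {
            "median_estimate": median,
            "relative_error": abs(median - t) / t,
        }
    return out


def planted_track_recovery(seed: int, n_replicates: int = 20, weight: float = 5.0,
                           n_samples: int = 60, n_permutations: int = 0) -> dict:
    """LASSO on per-bin amplicon-boundary counts with a planted
    breakpoint-propensity track among decoy features: fraction of
    replicates ranking the planted track first."""
    wins = 0
    for r in range(n_replicates):
        m = _one_track_replicate(seed + r, weight, n_samples, n_permutations)
        wins += m.ranked_features()[0] == "planted"
    return {"top_rank_fraction": wins / n_replicates, "n": n_replicates}


def null_track_calibration(seed: int, n_replicates: int = 20,
                           n_samples: int = 60, n_permutations: int = 200) -> dict:
    """With zero propensity weight, the fraction of replicates where no
    feature reaches permutation p < 0.05."""
    clean = 0
    for r in range(n_replicates):
        m = _one_track_replicate(seed + r, 0.0, n_samples, n_permutations)
        clean += not any(p < 0.05 for p in m.permutation_p.values())
    return {"clean_fraction": clean / n_replicates, "n": n_replicates}


def _one_track_replicate(seed: int, weight: float, n_samples: int,
                         n_permutations: int):
    config = SimConfig(propensity_weight=weight, randomize_boundaries=True)
    cohort = simulate_cohort(config, seed=seed, n_samples=n_samples,
                             mechanism_mix={MECH_TB: 1.0})
    layout = cohort.layout
    bins = bin_genome(layout, config.track_bin_kb * 1000)
    positions = []
    for s in cohort.samples:
        baselines = amp_mod.arm_baselines(s.segments, layout)
        for a in amp_mod.call_amplicons(s.segments, baselines, layout):
            positions.append((a.chrom, a.start))
            positions.append((a.chrom, a.end - 1))
    response = count_positions(bins, positions)
    order = layout.chromosomes
    features = {"planted": np.concatenate([cohort.track.scores[c] for c in order])}
    for i, decoy in enumerate(cohort.decoys):
        features[f"decoy{i + 1}"] = np.concatenate([decoy.scores[c] for c in order])
    return lasso_model(response, pd.DataFrame(features),
                       n_permutations=n_permutations, seed=seed)
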