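"""Mutational timing of copy-number gains.

A somatic SNV on a gained segment is either *pre-gain* (present on all
amplified copies, multiplicity ~ the major copy number), *post-gain or on
the minor allele* (multiplicity ~ 1), or *subclonal*. The point rule calls
a mutation pre-gain when its estimated multiplicity exceeds 0.75 x the
major copy number; a binomial likelihood over the three multiplicity
hypotheses gives calibrated posteriors.

The density of pre-gain mutations (the ancestral burden) converts to an
age through a linear clonal clock. Burdens are reported per diploid
genome: only mutations on the gained haplotype are amplified, so the
haplotype-specific pre-gain count is doubled (``diploid_factor = 2``)
before division by segment length — this matches a clock rate calibrated
on total clonal SNV counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .records import SampleInfo, SNVRecord

LABEL_PRE = "pre_amplification"
LABEL_POST = "post_or_minor"
LABEL_SUBCLONAL = "subclonal"

#: point-rule factor: pre-gain iff multiplicity > PRE_FACTOR * major CN
PRE_FACTOR = 0.75
#: copies assigned to the subclonal hypothesis
SUBCLONAL_COPIES = 0.5
#: minimum segment size for gain timing
MIN_SEGMENT_BP = 5_000_000


def mutation_multiplicity(vaf: float, purity: float, cn_total: float) -> float:
    """Estimated number of tumour DNA copies carrying the mutation:
    m = VAF * (purity * cn_total + 2 * (1 - purity)) / purity."""
    if not 0 < purity <= 1:
        raise ValueError(f"purity {purity} outside (0, 1]")
    return vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / purity


def expected_vaf(copies: float, purity: float, cn_total: float) -> float:
    """Expected VAF of a mutation on ``copies`` tumour copies of the locus."""
    return copies * purity / (purity * cn_total + 2.0 * (1.0 - purity))


@dataclass
class TimingCall:
    label: str
    multiplicity: float
    posteriors: dict[str, float]


def classify_snv_timing(
    snv: SNVRecord,
    major_cn: int,
    minor_cn: int,
    purity: float,
) -> TimingCall:
    """Classify one SNV on a gained segment.

    Hypotheses: multiplicity = major CN (pre-gain), 1 (post-gain or minor
    allele), and 0.5 copies (subclonal); binomial likelihoods with a
    uniform prior. Hypotheses implying an expected VAF > 1 are dropped.
    Posterior ties fall back to the 0.75-rule point estimate.
    """
    if major_cn < 1:
        raise ValueError("major_cn must be >= 1")
    cn_total = float(major_cn + minor_cn)
    m = mutation_multiplicity(snv.vaf, purity, cn_total)
    hyps = {LABEL_PRE: float(major_cn), LABEL_POST: 1.0, LABEL_SUBCLONAL: SUBCLONAL_COPIES}
    liks = {}
    for label, copies in hyps.items():
        v = expected_vaf(copies, purity, cn_total)
        if v > 1:
            continue
        liks[label] = float(binom.pmf(snv.alt_count, snv.total_depth, v))
    total = sum(liks.values())
    if total > 0:
        posteriors = {k: v / total for k, v in liks.items()}
        best = max(posteriors.values())
        winners = [k for k, v in posteriors.items() if v == best]
    else:  # all likelihoods underflow: fall back to the point rule
        posteriors = {k: float("nan") for k in liks}
        winners = []
    if len(winners) == 1:
        label = winners[0]
    else:
        label = LABEL_PRE if m > PRE_FACTOR * major_cn else LABEL_POST
    return TimingCall(label=label, multiplicity=m, posteriors=posteriors)


@dataclass
class BurdenEstimate:
    burden_per_mb: float
    n_pre: int
    n_total: int
    segment_mb: float
    ci: tuple[float, float]


def ancestral_burden(
    labels: Sequence[str],
    segment_lengths_bp: Sequence[int],
    diploid_factor: float = 2.0,
    n_bootstrap: int = 1_000,
    rng: Optional[np.random.Generator] = None,
) -> BurdenEstimate:
    """Pre-gain mutation density over the analysed segments, per diploid Mb.

    ``labels`` are per-SNV timing labels on the segments;
    ``segment_lengths_bp`` the analysed segment lengths. The bootstrap CI
    resamples SNV labels.
    """
    total_mb = sum(segment_lengths_bp) / 1e6
    if total_mb <= 0:
        raise ValueError("zero total segment length")
    labels = list(labels)
    is_pre = np.array([lab == LABEL_PRE for lab in labels], dtype=bool)
    n_pre = int(is_pre.sum())
    burden = diploid_factor * n_pre / total_mb
    if rng is None:
        rng = np.random.default_rng(0)
    if len(labels) == 0:
        ci = (0.0, 0.0)
    else:
        idx = rng.integers(0, len(labels), size=(n_bootstrap, len(labels)))
        boot = diploid_factor * is_pre[idx].sum(axis=1) / total_mb
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return BurdenEstimate(
        burden_per_mb=burden, n_pre=n_pre, n_total=len(labels),
        segment_mb=total_mb, ci=ci,
    )


@dataclass
class ClockModel:
    rate_per_year: float
    genome_mb: float
    eligible_samples: list[str]

    def __post_init__(self):
        if self.rate_per_year <= 0:
            raise ValueError("clock rate must be positive")


def clock_eligible(info: SampleInfo) -> bool:
    """Eligibility filters for clock calibration: purity >= 0.6, < 10,000
    SNVs, APOBEC (SBS2+SBS13) fraction < 0.5, no WGD, microsatellite
    stable, HR proficient, age known. Missing values fail the filter."""
    return (
        info.purity >= 0.6
        and info.snv_count is not None and info.snv_count < 10_000
        and info.sbs2_13_fraction is not None and info.sbs2_13_fraction < 0.5
        and info.wgd is False
        and info.msi is False
        and info.hr_deficient is False
        and info.age is not None
    )


def estimate_clock_rate(
    manifest: Sequence[SampleInfo],
    clonal_burdens: dict[str, float],
    genome_mb: float = 2_880.0,
    min_samples: int = 10,
) -> ClockModel:
    """Least-squares fit of clonal SNV count = rate x age through the origin
    over the eligible samples."""
    eligible = [s for s in manifest if clock_eligible(s) and s.sample in clonal_burdens]
    if len(eligible) < min_samples:
        raise ValueError(
            f"only {len(eligible)} samples pass the clock filters "
            f"(purity>=0.6, <10k SNVs, SBS2/13<0.5, no WGD, MSS, HR-proficient, age known); "
            f"need >= {min_samples}"
        )
    ages = np.array([s.age for s in eligible], dtype=float)
    burdens = np.array([clonal_burdens[s.sample] for s in eligible], dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError("degenerate fit: all eligible samples have the same age")
    rate = float(np.sum(ages * burdens) / np.sum(ages**2))
    return ClockModel(
        rate_per_year=rate, genome_mb=genome_mb,
        eligible_samples=[s.sample for s in eligible],
    )


def burden_to_age(
    burden_per_mb: float, genome_mb: float = 2_880.0, rate_per_year: float = 29.4
) -> float:
    """Convert a per-diploid-Mb ancestral burden to years:
    years = burden_per_mb * genome_mb / rate_per_year."""
    if rate_per_year <= 0:
        raise ValueError("rate_per_year must be positive")
    if genome_mb <= 0:
        raise ValueError("genome_mb must be positive")
    if burden_per_mb < 0:
        raise ValueError("burden must be non-negative")
    return burden_per_mb * genome_mb / rate_per_year


def order_gains(
    burdens_by_group: dict[str, Sequence[float]],
    min_group_size: int = 3,
    q_threshold: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order copy-number gain groups by median ancestral burden.

    Returns (medians, pairwise) where ``medians`` has the per-group median
    burden (sorted ascending = earliest first) and ``pairwise`` the
    two-sided rank-sum tests with Benjamini-Hochberg q-values.
    """
    groups = {}
    for name, vals in burdens_by_group.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size < min_group_size:
            warnings.warn(f"group {name!r}: n={vals.size} < {min_group_size}; excluded",
                          stacklevel=2)
            continue
        groups[name] = vals
    medians = pd.DataFrame(
        {"group": list(groups), "n": [len(v) for v in groups.values()],
         "median_burden": [float(np.median(v)) for v in groups.values()]}
    ).sort_values("median_burden", kind="stable").reset_index(drop=True)
    rows = []
    for a, b in combinations(sorted(groups), 2):
        stat, p = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(dict(group_a=a, group_b=b, statistic=float(stat), p=float(p)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    if len(pairwise):
        pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
        pairwise["significant"] = pairwise["q"] < q_threshold
    else:
        pairwise["q"] = pd.Series(dtype=float)
        pairwise["significant"] = pd.Series(dtype=bool)
    return medians, pairwise
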