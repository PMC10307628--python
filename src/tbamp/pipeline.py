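"""End-to-end orchestration: validated config, staged execution, summary.

Stages run in dependency order (amplicons -> boundaries -> tb -> timing),
write one TSV each, and contribute to a JSON run summary that records the
package version, seed, and a hash of the effective configuration, so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, amplicons as amp_mod, boundaries as bnd_mod, io as tio, tb as tb_mod
from .genome import read_genome_layout
from .timing import LABEL_PRE, ancestral_burden, burden_to_age, classify_snv_timing

_RANGES = {
    "tolerance_bp": (0, 10_000_000),
    "min_amplicon_bp": (1, 100_000_000),
    "fold": (1e-9, 100.0),
    "flank_margin": (0, 10),
    "foldback_window_bp": (1, 1_000_000),
    "min_sv": (1, 10_000),
    "proximity_bp": (1, 500_000_000),
    "loh_minor_max": (0.0, 0.5),
    "clock_rate_per_year": (1e-9, 1_000.0),
    "genome_mb": (1.0, 100_000.0),
    "bin_bp": (1, 100_000_000),
    "ratio_bin_bp": (1, 100_000_000),
    "k_groups": (1, 100),
    "q_threshold": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults, plus input paths."""

    cytoband: Optional[str] = None
    segments: Optional[str] = None
    svs: Optional[str] = None
    snvs: Optional[str] = None
    manifest: Optional[str] = None
    out_dir: str = "results"
    seed: int = 0
    # stage toggles
    run_amplicons: bool = True
    run_boundaries: bool = True
    run_tb: bool = True
    run_timing: bool = True
    # parameters
    tolerance_bp: int = 1_000
    min_amplicon_bp: int = 1_000
    fold: float = 3.0
    flank_margin: int = 1
    foldback_window_bp: int = 5_000
    min_sv: int = 10
    proximity_bp: int = 5_000_000
    loh_minor_max: float = 0.25
    clock_rate_per_year: float = 29.4
    genome_mb: float = 2_880.0
    bin_bp: int = 100_000
    ratio_bin_bp: int = 250_000
    k_groups: int = 4
    q_threshold: float = 0.10

    def __post_init__(self):
        for key, (lo, hi) in _RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"config {key}={v} outside allowed range [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analytical configuration (the output path is not
        part of the analysis)."""
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML config, filling defaults; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_effective_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run summary (also written
    to ``<out_dir>/summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # fail before any stage runs if an enabled stage lacks inputs
    if not (config.cytoband and config.segments):
        raise ValueError("cytoband and segments inputs are required")
    if config.run_boundaries and not config.svs:
        raise ValueError("boundary stage enabled but SV input missing")
    if config.run_timing and not (config.snvs and config.manifest):
        raise ValueError("timing stage enabled but SNV/manifest inputs missing")

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    write_effective_config(config, out / "effective_config.yaml")

    layout = read_genome_layout(config.cytoband)
    segments = tio.read_cn_segments(config.segments, layout)
    baselines = amp_mod.arm_baselines(segments, layout)

    amps = amp_mod.call_amplicons(
        segments, baselines, layout,
        min_size=config.min_amplicon_bp, fold=config.fold,
        flank_margin=config.flank_margin,
    )
    pd.DataFrame(
        [
            dict(sample=a.sample, chrom=a.chrom, arm=a.arm, start=a.start, end=a.end,
                 mean_cn=round(a.mean_cn, 4), baseline=a.baseline,
                 left_flank=a.left_flank, right_flank=a.right_flank,
                 eligible=a.eligible)
            for a in amps
        ]
    ).to_csv(out / "amplicons.tsv", sep="\t", index=False)
    summary["n_amplicons"] = len(amps)
    summary["n_eligible"] = sum(a.eligible for a in amps)

    classifications: list[bnd_mod.AmpliconClassification] = []
    if config.run_boundaries:
        svs = tio.read_sv_bedpe(config.svs)
        classifications = bnd_mod.classify_boundaries(
            amps, svs, tolerance_bp=config.tolerance_bp,
            foldback_window=config.foldback_window_bp,
        )
        pd.DataFrame(
            [
                dict(sample=c.amplicon.sample, chrom=c.amplicon.chrom,
                     start=c.amplicon.start, end=c.amplicon.end,
                     left_category=c.left.category, right_category=c.right.category,
                     category=c.category,
                     left_sv=c.left.sv.id if c.left.sv else "",
                     right_sv=c.right.sv.id if c.right.sv else "")
                for c in classifications
            ]
        ).to_csv(out / "boundary_calls.tsv", sep="\t", index=False)
        counts: dict[str, int] = {}
        for c in classifications:
            counts[c.category] = counts.get(c.category, 0) + 1
        summary["boundary_categories"] = counts

        if config.run_tb:
            clusters = tb_mod.cluster_svs(svs, layout, proximity_bp=config.proximity_bp)
            events = tb_mod.detect_tb_events(
                clusters, classifications, segments, layout,
                min_sv=config.min_sv, loh_minor_max=config.loh_minor_max,
                baselines=baselines,
            )
            by_sample: dict[str, list[tb_mod.TBEvent]] = {}
            for ev in events:
                by_sample.setdefault(ev.sample, []).append(ev)
            for evs in by_sample.values():
                tb_mod.partition_rounds(evs)
            pd.DataFrame(
                [
                    dict(sample=ev.sample, n_sv=ev.cluster.n_sv,
                         chromosomes=",".join(sorted(ev.cluster.chromosomes)),
                         bridge_arms=",".join(f"{c}{a}" for c, a in ev.bridge_arms),
                         dual_loh=ev.dual_loh, extensive=ev.extensive,
                         round_id=ev.round_id,
                         mean_loh_fraction=round(
                             float(np.mean(list(ev.loh_fractions.values()))), 4))
                    for ev in events
                ]
            ).to_csv(out / "tb_events.tsv", sep="\t", index=False)
            summary["n_tb_events"] = len(events)
            summary["n_tb_samples"] = len(by_sample)

    if config.run_timing:
        snvs = tio.read_snv_table(config.snvs)
        manifest = {m.sample: m for m in tio.read_manifest(config.manifest)}
        rng = np.random.default_rng(config.seed)
        rows = []
        seg_index = [
            s for s in segments
            if s.length > 5_000_000 and amp_mod.round_half_up(s.cn_major) >= 2
        ]
        for seg in seg_index:
            info = manifest.get(seg.sample)
            if info is None:
                continue
            major = amp_mod.round_half_up(seg.cn_major)
            minor = amp_mod.round_half_up(seg.cn_minor)
            labels = [
                classify_snv_timing(v, major, minor, info.purity).label
                for v in snvs
                if v.sample == seg.sample and v.chrom == seg.chrom
                and seg.start < v.pos <= seg.end
            ]
            if not labels:
                continue
            est = ancestral_burden([lab for lab in labels], [seg.length],
                                   n_bootstrap=200, rng=rng)
            rows.append(
                dict(sample=seg.sample, chrom=seg.chrom, start=seg.start, end=seg.end,
                     major_cn=major, n_snv=len(labels),
                     n_pre=sum(lab == LABEL_PRE for lab in labels),
                     burden_per_mb=round(est.burden_per_mb, 4),
                     age_years=round(
                         burden_to_age(est.burden_per_mb, config.genome_mb,
                                       config.clock_rate_per_year), 2))
            )
        pd.DataFrame(rows).to_csv(out / "gain_timing.tsv", sep="\t", index=False)
        summary["n_timed_segments"] = len(rows)
        if rows:
            summary["median_gain_age_years"] = float(
                np.median([r["age_years"] for r in rows])
            )

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
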