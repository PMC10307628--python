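# tbamp — translocation-bridge amplification analysis

`tbamp` is a Python toolkit for dissecting **focal oncogene amplifications**
in cancer whole genomes. Given allele-specific copy-number segments, SV
breakends with supporting-fragment counts, and somatic SNVs with allele
depths, it:

* calls **focal amplicons** — segments with copy number > 3× the
  chromosome-arm baseline (the length-weighted modal integer CN of the arm,
  with haploid arms treated as diploid);
* classifies the SVs at amplicon boundaries into six categories —
  fold-back inversion, translocation, double minute, tandem duplication,
  intra-chromosomal complex, no SV support — which are diagnostic of the
  amplification mechanism (fold-backs ⇒ breakage–fusion–bridge;
  boundary translocations ⇒ translocation–bridge);
* detects **translocation–bridge (TB) amplification footprints**:
  multi-chromosome rearrangement clusters (≥ 10 SVs) with boundary
  translocations, annotated with the model's tell-tale *dual-LOH* pattern —
  telomeric loss of heterozygosity on both bridge arms, heterozygosity
  retained on the non-bridge arms;
* **times copy-number gains** with a clonal mutation clock: an SNV with
  multiplicity `m = VAF·(p·CN_t + 2(1−p))/p` above `0.75 × CN_major` is a
  pre-gain mutation, and the pre-gain density per diploid Mb converts to
  years as `age = burden × G / r` (defaults `G = 2,880` Mb, `r = 29.4`
  clonal SNVs/yr);
* models **boundary and breakpoint hotspots** against epigenomic feature
  tracks: one-sided Fisher overlap on 100-kb bins, cross-validated LASSO
  with VIF diagnostics and maxT permutation significance, fourfold
  treated/control hotspot calling with bait masking, pre-ranked gene-set
  enrichment, and a receptor-activity expression score.

Because the WGS cohorts this methodology targets are controlled-access, the
package includes a **mechanism simulator** (TB, BFB, chromothripsis, tandem
duplication, double minute, plus a clock SNV process) that emits
pipeline-ready files with ground truth; every quantitative claim in the
test suite is a recovery experiment against it. See `docs/methods.md` for
the full model descriptions and design rationale.

## Worked example

Simulate a small cohort and run the pipeline end to end:

```bash
tbamp simulate --seed 17 --n-samples 20 --out scratch/demo
tbamp call-amplicons --segments scratch/demo/segments.tsv \
    --cytoband scratch/demo/genome.cytoband.tsv --out scratch/demo/amplicons.tsv
tbamp detect-tb --sv scratch/demo/svs.bedpe --segments scratch/demo/segments.tsv \
    --cytoband scratch/demo/genome.cytoband.tsv --out scratch/demo/tb.tsv
```

The numbered scripts under `analysis/` run the same stages as a narrated
analysis (01 simulate → 02 amplicons → 03 boundaries → 04 TB detection →
05 gain timing → 06 enrichment). On the default 40-tumour cohort
(seed 17: 16 TB, 12 BFB, 12 chromothripsis) they print:

```
44 amplicons in 28 samples
  44 (100%) border an unamplified region and enter boundary analysis

boundary categories by generative mechanism:
category        fold_back  translocation
true_mechanism
BFB                    12              0
TB                      0             32

16 TB footprints in 16 samples (16 true TB samples)
  sensitivity 1.00, specificity 1.00
  dual-LOH in 100% of events; mean bridge-arm LOH fraction 0.60

clock calibration: 29.4 clonal SNVs/yr (150 eligible samples, generative rate 29.4)
timed 16 TB samples with non-bridge gains: median |relative error| 17%
worked example: 0.52 SNVs/Mb x 2,880 Mb / 29.4 per yr = 50.9 years (~51)
```

Reading the output: every BFB amplicon is recognized by its fold-back
boundaries and every TB amplicon by its boundary translocations; all 16 TB
events show the dual-LOH footprint; and the headline conversion — a median
ancestral burden of 0.52 SNVs/Mb under a 29.4 SNVs/yr clonal clock — places
the typical bridge breakage at about 51 years of age.

The planted-track experiment (`analysis/06_enrichment.py`) shows the LASSO
ranking the planted breakpoint-propensity track first among decoys
(coefficient 0.0097, maxT permutation p = 0.005, VIF 1.6) and calls 666
fourfold hotspot bins with the bait ±1 Mb masked.

## Layout

```
src/tbamp/        library: genome/records/io, amplicons, boundaries, tb,
                  timing, enrichment, sim, validation, pipeline, cli
analysis/         numbered narrative drivers writing results/
scripts/          acceptance.py (validation re-run)
tests/            pytest suite incl. brute-force oracles and property tests
docs/methods.md   models, parameters, numerical choices, limitations
```
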