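# Methods

`tbamp` analyses focal oncogene amplifications in cancer genomes from three
inputs a standard somatic-calling stack already produces: allele-specific
copy-number segments, structural-variant (SV) breakend pairs with supporting
read-fragment counts, and somatic SNVs with allele depths. Because the kind
of whole-genome data the method targets is controlled-access, the package
ships a generative simulator of the amplification mechanisms; every
quantitative claim the test suite and `scripts/acceptance.py` make is a
recovery experiment against that simulator's ground truth.

## Coordinates and conventions

All intervals are 0-based half-open; SNV positions are 1-based (VCF
convention) and converted exactly once where they are intersected with
intervals. Chromosome names are normalized to bare form (`chr17` → `17`).
Breakend orientation uses `{L, R}`: `L` means the sequence to the left
(lower coordinate) of the position is retained at the junction, `R` the
sequence to the right. In BEDPE, strand `+` maps to `L` and `-` to `R`.
Under this vocabulary a deletion-like junction is (L, R), a head-to-tail
duplication-like junction is (R, L) with pos1 < pos2, and fold-back
junctions are (L, L) or (R, R). This removes the head/tail ambiguity of
BEDPE dialects.

## Amplicon calling

The baseline copy number of a chromosome arm is the integer copy number
supported by the largest combined span of segments on the arm. Segment
totals are rounded to the nearest integer (half up — segmented real-valued
CN needs an explicit rule; ties between integers with equal span resolve to
the smaller). Arms whose modal copy number is 0 or 1 are treated as diploid,
so a lost arm does not make ordinary two-copy segments look "amplified".
Arms with no segments inherit the whole-chromosome tally.

A focal amplicon is a maximal run of segments with total CN strictly greater
than 3× the arm baseline. "Contiguous" means abutting coordinates; a
configurable merge gap (default 0 bp) is exposed for ragged segmentations.
Merged regions shorter than 1 kb are dropped; the amplicon CN is the
length-weighted mean. A flank is *unamplified* when the abutting segment's
rounded CN is at most one copy above the baseline (one extra copy is allowed
because unequal breakage of the two flipped dicentrics duplicates a
segment); sides with no abutting segment are the structural boundary the
amplicon runs into (telomere or centromere). Only amplicons with at least
one unamplified flank enter boundary analysis — an amplified segment inside
a broadly amplified neighbourhood has no interpretable edge.

## Boundary SV taxonomy

A breakend matches an amplicon edge when it lies within a matching tolerance
(default 1,000 bp; set near 0 for segmenter-concordant inputs) *and* its
orientation retains the amplified side (left edge → `R`, right edge → `L`).
The orientation requirement is not part of the verbal definition of a
boundary SV but suppresses coincidental matches; candidates are ranked by
supporting fragments, then distance.

Each edge is classified with a fixed precedence:

1. **fold-back inversion** — intra-chromosomal, same orientation on both
   breakends, breakends < 5 kb apart (the BFB hallmark);
2. **translocation** — inter-chromosomal (the TB hallmark);
3. one intra-chromosomal (R, L) junction matching *both* edges (the
   self-ligation signature): **double minute** if the amplicon CN exceeds 3×
   the rounded adjacent-segment CN, else **tandem duplication**;
4. **intra-chromosomal complex** otherwise;
5. **no SV support** when nothing matches.

The per-amplicon category is the highest-precedence edge category. The
precedence puts mechanism-diagnostic categories first; it matters only when
the two edges disagree, and both per-edge and per-amplicon labels are
emitted.

Read-amplified SVs are separated from background by a tumour-specific
threshold at the inflection of the ascending sorted support curve,
operationalized as the support value at the largest positive second forward
difference. When no positive second difference exists (e.g. all supports
equal) the threshold falls back to twice the sample median, which flags
nothing in the degenerate case. Fewer than five positive-support SVs → all
flagged non-amplified with a warning.

Pan-cancer views aggregate per-tumour-type fractions of the amplicon-level
categories (types with < 10 classified amplicons excluded) and cluster types
on their (fold-back, translocation, double-minute) fractions with
average-linkage agglomerative clustering on Euclidean distances, cut at k
groups (default 4).

## TB footprint detection

SVs are clustered per sample by union–find over three rules that
approximate full phasing-based clustering: (a) breakends on one chromosome
within 5 Mb; (b) translocations joining the same unordered pair of
chromosome arms; (c) all fold-back inversions on one arm. A cluster is a
TB-amplification footprint when it contains ≥ 10 SVs, involves ≥ 2
chromosomes, and contains at least one amplicon-boundary translocation.

Bridge arms are the arms carrying boundary-translocation breakends (when
more than two arms are touched, all are reported). Each bridge arm is
annotated with its telomeric LOH: the maximal run of segments with minor CN
≤ 0.25 walking inward from the telomere, as a fraction of the arm length.
Focally amplified segments (total CN > 3× arm baseline) neither extend nor
interrupt this run: amplified copies are extrachromosomal or ectopic, and in
both the simulator's TB daughters and real bridge arms the focal amplicon
(minor CN 1, contributed by the intact homologue) sits *inside* the LOH
span; a literal contiguity rule would truncate the LOH at the amplicon and
misstate the arm's hemizygosity. `dual_loh` requires telomeric LOH on bridge
arms of at least two distinct chromosomes. A footprint is *extensive* when
≥ 10 cluster translocations join the involved chromosomes (all cluster
translocations are counted, not only read-amplified ones). Independent
amplification rounds are the connected components of the
chromosome graph whose edges are cluster translocations.

The case–control screen takes user-supplied binary alteration flags (driver
calling is upstream), keeps the top 10% most frequently altered genes per
alteration class, drops genes altered in < 5% of samples, and tests each
against the extensive-TB label with a two-sided Fisher's exact test and
Benjamini–Hochberg correction (significant at q < 0.1). Degenerate tables
report a Haldane-corrected (+0.5) odds ratio and are flagged.

## Mutational timing

The multiplicity of an SNV (copies of the locus carrying it) is
`m = VAF × (p·CN_t + 2(1−p)) / p` with tumour purity `p` and local total CN
`CN_t`. The point rule calls a mutation pre-gain when `m > 0.75 × CN_major`.
Posterior labels come from binomial likelihoods of the alt count under three
multiplicity hypotheses — the major CN (pre-gain), 1 (post-gain or minor
allele), and 0.5 copies (a fixed subclonal hypothesis that simplifies the
full mixture treatment) — with a uniform prior; ties fall back to the point
rule. Posteriors sum to one by construction. At depth 60 and purity 0.7 the
1-copy and 0.5-copy likelihoods overlap appreciably, so three-way accuracy
plateaus near 0.91 while the pre-vs-not-pre dichotomy — the axis the burden
estimate uses — is ≈ 0.98; both are asserted in the tests.

The ancestral burden of a gained region is the density of pre-gain
mutations per **diploid** Mb: only mutations on the gained haplotype are
amplified, i.e. roughly half of the mutations present at the gain, so the
pre-gain count is multiplied by 2 (exposed as `diploid_factor`) before
dividing by the segment length. Without this correction a clock calibrated
on total clonal SNV counts would halve every age. Gains are timed only on
segments > 5 Mb; confidence intervals bootstrap the SNV labels (1,000
resamples, seeded).

The clonal clock is fit through the origin (count = rate × age) on samples
passing six filters: purity ≥ 0.6, < 10,000 SNVs, APOBEC (SBS2+SBS13)
fraction < 0.5, no whole-genome duplication, microsatellite stable, HR
proficient — signature fractions and the WGD/MSI/HR flags are consumed as
precomputed annotations. An intercept-free fit keeps the single rate
identifiable; a cohort with a single age value is rejected as degenerate.
Ages follow as `burden_per_mb × genome_mb / rate`, with `genome_mb = 2,880`
by default: the constant is not standard anywhere, but 0.52/Mb ↔ 51 years at
29.4/yr implies ≈ 2,880 Mb (an autosomal non-N scale), and the default is
chosen to be consistent with that worked example. Whether published per-Mb
burdens are haploid- or diploid-normalized is genuinely ambiguous; this
package is internally consistent on the diploid scale and flags the
constant as configurable. Cohort-level gain ordering uses per-group medians
with pairwise two-sided rank-sum tests and BH correction (q < 0.1); groups
with n < 3 are excluded.

## Bin-level enrichment

The genome is tiled in fixed-width half-open bins (100 kb for boundary
modelling, 250 kb for induced-break ratios; terminal bins truncated).
Feature tracks are summarized per bin as overlap indicators (peak tracks)
or coverage-weighted mean scores (signal tracks). Univariate association is
a one-sided Fisher's exact test on the bins' peak × target 2×2 table;
degenerate margins get the Haldane odds ratio and a flag.

The multivariate model is a LASSO on standardized features with the penalty
chosen by seeded 5-fold cross-validation. Collinearity is reported as
variance inflation factors computed on the unpenalized standardized design
(perfectly collinear features report ∞). Per-feature significance uses
response-permutation refits at the selected penalty, compared against the
permuted **maximum** |coefficient| over features (Westfall–Young maxT).
The maxT form is deliberate: chromatin features are correlated, per-feature
marginal permutation p-values are uniform under the null (so with ~6
features some track would reach p < 0.05 in ~a quarter of null datasets),
and family-wise calibration is what makes "the top-ranked track is real"
a defensible claim. Features shrunk to zero get p = 1.

Treated/control breakpoint ratios use a pseudocount of 1 (zero-count bins
are otherwise undefined); bins within ±1 Mb of the bait interval are masked
and can never be hotspots; the hotspot rule is strictly greater than
fourfold. Gene-set enrichment on ranked per-gene scores is a weighted
Kolmogorov–Smirnov running sum (weight = |score|) with membership-label
permutation; |ES| is compared so the null is calibrated regardless of the
deviation's sign.

Receptor-driven transcriptional activity is scored as the fraction of a
responsive-gene set expressed at or above the gene's **cohort-wide** median
(inclusive, so a sample exactly at every median scores 1.0; the
per-sample-percentile alternative is exposed by computing against any other
reference). The set itself is derived from candidates by a two-sided
rank-sum test between receptor-positive and -negative samples (BH q < 0.05,
higher median in the positive group).

## The simulator

The simulator emits complete per-sample inputs — tiled allele-specific CN
segments, canonical SVs with support counts, clock SNVs with read depths —
plus a truth object labelling every event, SV and SNV. One haplotype is
designated the rearranged one; the other stays at one copy, which keeps
`cn_major + cn_minor = cn_total` exact before measurement noise (Gaussian,
σ = 0.05 on each allele; SV breakends jittered ±60 bp against segment
edges; both well inside the 1 kb matching tolerance and the 0.25 LOH
threshold).

**TB amplification** follows the dicentric-bridge model: a G1 translocation
joins the distal q arms of two oncogene-bearing chromosomes (chains longer
than two are resolved to one dicentric with balanced intermediate
translocations); the acentric distal pieces are lost; after replication the
anti-parallel sister dicentrics each break once, uniformly along the
inter-centromeric bridge; the emitted daughter is the one inheriting two
complementary hemi-dicentrics, which *always* has telomeric LOH on both
bridge arms and full heterozygosity on both non-bridge arms (the dual-LOH
theorem, asserted for every draw); the oncogene fragment between the two
sister breakpoints circularizes into ecDNA at a log-uniform 10–100 copies,
bounded by two inter-chromosomal junctions (the original translocation and
the circularization junction) whose support scales with the copy number
(≈ 3 fragments per copy over a background of ~10, so a 20-copy ecDNA's
boundary support is ≥ 5× the background median). Poisson(20) unamplified
internal rearrangements, Poisson(3) extra bridge-arm translocations (≥ 10
under the *extensive* preset) and Poisson(25) genome-wide background SVs
complete the sample. Conditioning the two uniform sister breakpoints on the
emitted-daughter geometry is done by direct draws from the conditional
(uniform on the allowed intervals), which is exactly equivalent to rejection
sampling but never fails. Only this daughter is emitted by default — it is
the observed footprint; no micronucleation or second-round chromothripsis
of the hemi-dicentrics is modelled.

Oncogenes sit at 0.95 of the q arm by default. The placement is the one
modelling choice tuned to an abstract criterion rather than to a specific
locus: with the amplified neighbourhood near the distal end of the bridge,
a uniform bridge breakpoint translates into a telomeric LOH fraction that is
nearly uniform on (0, 1), reproducing the ~50%-of-the-arm average LOH the
dicentric model predicts; proximal oncogene placement would bias LOH
fractions high. Real bridge arms have oncogenes at various arm positions;
the simulator abstracts the arm coordinate rather than any particular gene.

**BFB** (chromatid type) runs 3–5 break–fusion–bridge cycles on one q arm:
stair-step CN doubling toward the most recent break, (R,R)/(L,L) fold-back
junctions < 5 kb wide at each step, and single-arm telomeric LOH distal of
the initiating break. **Chromothripsis** fragments one arm into 12–25
pieces, drops each with probability ½ (oscillating CN), and joins edges
with random orientations — confined to one chromosome, so it must never be
detected as TB. **Tandem duplication** raises a focal segment to CN 7
inside an already-duplicated (CN 3) neighbourhood with one (R,L) junction;
**simple double minute** raises a focal segment to 10–100 copies over a
diploid neighbourhood with one (R,L) junction. These four mechanisms plus
TB give the classifier's confusion experiment its four expected categories.

**Clock SNVs** accumulate at 29.4/2,880 ≈ 0.0102 SNVs per diploid Mb per
year (the clonal rate implied by the timing worked example), half per
haplotype. On a region whose rearranged haplotype reached `a` copies at
event age `t`: mutations before `t` on that haplotype are carried by all
`a` copies; later mutations (rate × `a`, one copy each) and all mutations
on the intact haplotype have multiplicity 1; lost-haplotype mutations are
unobservable. A Poisson(0.05/Mb) subclonal admixture sits at half a copy's
expected VAF. Reads are binomial at fixed depth 60 and purity 0.7;
zero-alt draws are dropped (a caller would not report them). Patient ages
are N(55, 8) clipped to [30, 80]; event ages default to U(0.3, 0.7) of the
patient's age; non-bridge-arm gains (one extra copy of both p arms) follow
bridge breakage by U(0, 5) years.

An optional breakpoint-propensity track (blocky, ~15% of 1-Mb blocks hot)
reweights all breakpoint draws by `1 + w × score`; in this mode amplicon
loci roam the genome instead of sitting at fixed oncogenes, so the planted
signal is identifiable. Decoy tracks mix the planted track (ρ = 0.2) with
independent noise.

**What the simulator does not emulate** — and hence what green tests do not
show about real data: segmentation errors and breakpoint offsets beyond
small jitter, subclonal copy-number states, whole-genome duplication,
multi-generation evolution (one driver event per sample), reciprocal
daughters and derivative-chromosome micro-structure, replication-timing or
mappability covariates, and any sequence-level effect. Recovery rates
reported here are upper bounds for well-segmented, single-event genomes.

## Problem sizes

The validation experiments are sized to be decisive yet quick on one CPU:
200 events for mechanism classification (50 per mechanism), 150 samples for
TB detection (50 per group), 500 draws for the dual-LOH theorem, 150
samples for clock calibration, ~5,000 SNVs for label accuracy, 3 × 50
replicates for age recovery, and 20 replicates each for the planted-track
and null-track LASSO studies (60 TB samples per replicate, 200 permutations
in the null study). The whole suite runs in well under five minutes.

## Known limitations

LINX-style phasing is approximated by three clustering rules; ecDNA
internal structure is not reconstructed; the amplified-SV inflection
heuristic formalizes a visual judgement and can be unstable for flat
support curves (the fallback is documented above); the subclonal timing
hypothesis is a single fixed 0.5-copy state; and the 2,880-Mb genome
constant inherits the haploid/diploid ambiguity discussed in the timing
section.
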