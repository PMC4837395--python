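# Methods

This note records the models, the defaults and why they are set where they
are, the numerical choices, and what the synthetic data do and do not
establish.

## Coordinates and dialects

Internal coordinates are 0-based half-open (BED-style) everywhere; the CpG
report dialect is 1-based (the `pos` column is the cytosine position) and is
converted only at the interval-assignment boundary. A gene's TSS is stored
0-based: BED start on `+`, end − 1 on `−`. CpG sites are keyed per strand;
symmetric CpG pairs are *not* merged — coverage filtering and testing treat
each strand's calls as read. Promoters are derived, never read:
[tss − 2000, tss + 500) on `+`, mirrored to [tss − 500, tss + 2001) on `−`
(one bp longer so the window always contains the TSS base). Both window arms
are knobs (`promoter_upstream/downstream`); −2000/+500 is a common
convention rather than a biological claim. miRNA TSS windows are symmetric
[tss − 2000, tss + 2001). Region membership is by cytosine position,
strand-independent, and deliberately non-exclusive: a CpG inside two
overlapping regions counts in both.

## Differential methylation

Per region with ≥ `min_cpgs` (default 5) shared CpGs, the paired differences
dᵢ = β_B,i − β_A,i give the effect size median(dᵢ) and a two-sided Wilcoxon
signed-rank p. Zeros are dropped; midranks handle ties. For ≤ 25 non-zero
differences the p-value is the exact two-tail probability
P(W⁺ ≤ min(w⁺, w⁻)) + P(W⁺ ≥ max(w⁺, w⁻)), computed by a
dynamic-programming convolution over integer (doubled) rank weights that is
equivalent to enumerating all 2ⁿ sign assignments; beyond 25 a normal
approximation with continuity and tie corrections is used. Significance
requires |median Δβ| > 0.20 **and** p < 0.01, both strict, with no
multiplicity correction across regions (each region is reported against the
raw 0.01 level). Note the exact test's granularity: with n = 5–7 pairs the
smallest attainable two-sided p is 1/16, 1/32 or 1/64, so tiny regions can
never reach p < 0.01; `min_cpgs` = 5 keeps them reportable while the
simulator plants ≥ 20 CpGs per region.

The signed-rank choice (rather than, say, Fisher's method over per-site
tests or a smoothing scan) matches the design: one sample per condition,
paired per-CpG observations, and a median-based effect criterion.

## Differential expression

With a single library per condition the count split of each feature is, under
the null of equal relative abundance, binomial given the total: p comes from
an exact two-sided binomial test of x₂ successes in x₁ + x₂ trials against
p₀ = N₂/(N₁ + N₂), the classic no-replicate RNA-seq contrast. Two-sidedness
follows the minimum-likelihood convention (sum of all outcome probabilities
≤ the observed one). BH adjustment runs across tested features only;
features with zero counts in both conditions are untested (p = 1, log₂FC = 0,
excluded from the multiplicity). The fold change uses a pseudocount of 1.0
on both sides — applied to the fold change only, never to the test — to
avoid infinite ratios. Significance: FDR ≤ 0.001 and |log₂FC| ≥ 1. mRNAs and
miRNAs use identical machinery and thresholds.

This exact test models sampling noise only; it is anticonservative against
biological replication noise. That is a property of the no-replicate design
itself, and the simulator is built to match it (below).

## Integration

Each comparison has one sample per condition, so "negative correlation" is
implemented as strict direction opposition of significant calls, not a
correlation coefficient: hyper ↔ down / hypo ↔ up for methylation vs
expression, up ↔ down for miRNA vs target. The consensus target map keeps
(miRNA, gene) pairs predicted by ≥ 2 distinct sources (multiplicity counts
sources, not rows). Double-regulated genes require significant DE, an
anticorrelated *promoter* DMR (gene-body methylation excluded — its
regulatory sign is ambiguous, and the gene-body relationship is summarised
separately with the `sign="pos"` matcher), and ≥ 1 anticorrelated consensus
miRNA. The "overall methylation" of a miRNA's TSS window is the
coverage-weighted mean β difference (weights = summed read depth of the two
samples); an unweighted mean is emitted alongside, and the
direction-stratified summary reports both mean and median across miRNAs
since either aggregation is defensible. Comparisons are intersected by gene
id only — the supporting evidence may differ between comparisons.

## Signature selection and classifiers

Selection: per candidate gene, a two-sided Mann–Whitney U test between
resistant and sensitive patients; retain p < 0.10; direction = sign of
(median resistant − median sensitive). The permissive 0.10 level reflects
the selection step's screening role (n = 27); the test and threshold are
knobs (`test="ttest"`, `selection_p_max`), and an optional direction-
concordance filter against expected directions is off by default. The
packaged 17-gene table (p-values 0.004–0.094) is the reference signature.

Bayesian binary regression is implemented as its deterministic MAP skeleton:
genes are z-scored with training statistics (SD with ddof = 1); the training
matrix's SVD supplies right-singular "metagene" directions; sample scores on
the top k directions (smallest k explaining ≥ 90% variance, capped at 3 and
at min(n − 1, p)) enter a probit regression with a N(0, λ⁻¹I) prior
(λ = 1) on all coefficients including the intercept, fit by Newton/Fisher
scoring (tolerance 1e−8 on the step norm, max 100 iterations,
non-convergence raises with the iteration count). The prior guarantees
finite coefficients on separable data. A full posterior simulation would add
uncertainty bands but not change the point classification; k, λ and the 0.5
probability threshold are exposed.

Hierarchical clustering uses 1 − Pearson correlation between patients over
the signature genes, average linkage, a 2-cluster cut, and majority true
labels per cluster; a tie labels resistant the cluster containing the
patient with the highest mean direction-signed z-score. Constant patient
vectors (undefined correlation) raise, naming the patient.

"k-nearest neighbour versus the class-average expression" is read literally
as nearest-centroid with two prototypes: class means of reference-z-scored
expression, Euclidean distance, exact ties → sensitive. A true kNN over
reference patients (`knn_classify`) is available for comparison.

All three classifiers are invariant to positive rescaling of the expression
matrix (z-scoring / correlation distance), and the probit model is
label-swap symmetric (probabilities map to their complements).

## Survival and odds ratios

Kaplan–Meier estimation and the log-rank test delegate to lifelines
(product-limit; censorings at an event time remain at risk for that event;
Σ(O − E) with hypergeometric variance, p from χ²₁). Odds ratios are ad/bc
with a Woolf (log-normal) 95% CI; any zero cell triggers the
Haldane–Anscombe +0.5 on all four cells. Pooling is Mantel–Haenszel (via
statsmodels) — the pooled estimator is unstated territory in forest-plot
practice, and MH is the standard fixed-effect choice — while the *displayed*
per-dataset weights are simply nᵢ/Σn, each dataset's share of the total
cases. Endpoint names (RFS vs DRFS) are metadata; both are (time, event)
pairs.

## The simulator

The generator is a pure function of (config, seed) and emulates the study
design at desk scale: a toy linear chromosome with 300 non-overlapping genes
(utr5/cds/intron/cds/intron/utr3 tiling, random strand) and 60 intergenic
miRNA TSSs; one sensitive baseline (WT) and two resistant lines whose
planted effects are shared with probability 0.8 (lines derived from a common
parent respond similarly); planted region Δβ = 0.35 on 10% of regions with
20–60 CpGs each at ~Poisson(20) read depth; planted |log₂FC| = 2 at library
sizes 10⁷ (mRNA) and 2·10⁷ (miRNA); three target-prediction sources in which
true pairs appear in ≥ 2 sources and decoys in exactly one; and a labelled
cohort of 13 sensitive + 14 resistant patients.

Two modelling choices matter for calibration:

* **Counts.** Each feature's abundance is log-normal multiplied by a
  gene-level Gamma(1/φ, φ) factor (φ = 0.05) shared by all libraries, with
  per-library Poisson sampling. Marginally every count is negative-binomial
  with dispersion φ, but cross-library null differences carry Poisson noise
  only — the regime the no-replicate exact test assumes. Drawing independent
  NB noise per library instead would make the exact test's null calibration
  impossible by construction (~3% of null features would pass FDR ≤ 0.001
  with |log₂FC| ≥ 1), which is a statement about the test, not about planted
  effects; the shared-factor form keeps the null clean while preserving the
  marginal count distribution.
* **Methylation.** Region baseline β (Beta(2, 2); planted regions draw from a
  mid-range uniform so the full ±0.35 shift is expressible without clipping)
  plus per-site jitter (SD 0.05) is shared across the three lines; read
  depths and methylated counts are binomial per line. Null paired
  differences therefore carry only binomial sampling noise, matching the
  signed-rank null. β values pushed outside [0, 1] by planting are clipped
  and counted. Background DMRs are planted only on gene-body features that
  do not overlap their gene's promoter window, so a promoter's methylation
  is only ever shifted by its own planting and the planted-truth bookkeeping
  stays exact.

The per-line truth sets (double-regulated genes, methylation-regulated
miRNAs) are *derived* from the planted components with the pipeline's own
sign rules — chance combinations of background plants count as truth, so
recovery metrics measure detection, not bookkeeping luck. The patient cohort
uses symmetric class means ∓/± (effect_sd/2)·direction per gene (separation
= effect_sd = 2.0 by default): with a one-sided parameterisation the
sensitive class would be patternless noise, mutual patient correlations ≈ 0,
and correlation-distance clustering would have no second cluster to find —
the symmetric form is what makes the two-class geometry the classifiers
assume. Survival is exponential with resistant hazard = 3× the sensitive
baseline (1/24 per time unit); censoring is independent uniform with its
upper bound solved (Brent) so the expected sensitive-class censored fraction
equals `censor_rate` = 0.3.

What the synthetic data do **not** emulate: realistic genome coordinates or
sequence, CpG-island structure, transcript isoforms, batch effects,
cross-platform (microarray ↔ RNA-seq) shifts, and biological replicate
variability beyond the shared-factor form above. Passing tests therefore
demonstrate that the machinery recovers the planted structure under its own
model assumptions at desk scale — not that real cell-line data would yield
comparable sensitivity.

## Problem sizes and determinism

The default simulated study (300 genes, 60 miRNAs, ~85k shared CpGs) runs
the full pipeline in a few seconds; the test suite uses a 40-gene version of
the same conditions for most fixtures and the default scale for the
planted-recovery check. The documented training-cohort runs use seed 11.
Every generator consumes a `numpy` `SeedSequence` derived from (seed, stage
tag), so outputs are byte-stable across runs and platforms; pipeline TSVs
are written with a fixed float format to keep reruns byte-identical.

## Known limitations

Per-region DMR p-values are reported without multiplicity correction (the
stated criterion is a raw 0.01); the exact binomial DE test inherits the
no-replicate design's blindness to biological variance; signature selection
reuses the cohort later used for in-sample classification (training-set
accuracy, as reported — external validation needs independent cohorts);
nearest-centroid inherits the reference cohort's z-scoring and will misfire
if query data are on a different scale with different gene variances.
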