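# Methods

## Arm-status model

All copy-number input is gene-level thresholded calls in {−2, −1, 0, +1, +2}
(deep deletion, shallow deletion, neutral, gain, amplification).  No base-pair
coordinates are modeled: arm membership comes entirely from the annotation's
chromosome/arm/cytoband columns, which sidesteps 0/1-based coordinate
questions and matches the resolution of the data.  "Deleted" always means
call ≤ −1 — shallow and deep deletions are both deletion events for the
arm-fraction computation, while they are separate event classes for the
differential tests.

The threshold classifier works on two per-sample fractions, f_del and f_homo
(definitions in the README).  Decision order and boundary semantics:

1. f_homo > 0.50 → excluded (homozygous whole-arm loss is a biologically
   distinct, rare event and is removed before cohorts are formed);
2. lost at the high cutoff — **inclusive** (≥ 0.97) for the HPV-negative
   policy, **strict** (> 0.50) for the HPV-positive policy;
3. preserved below the low cutoff (< 0.01);
4. otherwise excluded as intermediate.

Both policies and the boundary rule are fields of `ThresholdPolicy` and can
be overridden.  The fragile-site definition takes the median thresholded
call over the 3p14.2 locus genes; with an even locus size and a half/half
split the median falls at −0.5 > −1 and the sample is called preserved — the
tie resolves toward no loss.  The locus gene list is user-supplied (default:
every gene annotated to 3p14.2); median of thresholded calls is used because
thresholded calls are the only data type the package consumes.

Percent genome altered is gene-count-based: the fraction of universe genes
with a non-neutral call.  Segment lengths are unavailable at this
resolution, so this proxy is the definition, not an approximation of
another one.  Sex chromosomes are excluded from the default universe and
whole arms can be excluded (e.g. 3p itself when contrasting by 3p status);
both are options, since reasonable cohorts differ here.

## Statistical kernel

* **Fisher 2×2** — two-sided by the probability-mass rule: sum the
  hypergeometric probabilities of all margin-fixed tables no more probable
  than the observed one (the convention of mainstream statistics software;
  the doubling rule is a known alternative and is not used).  Effect:
  conditional-MLE odds ratio with 95% CI; large per-gene screens use the
  cross-product odds ratio to avoid the root-finding cost.  A zero margin
  returns p = 1 with a warning rather than an error.
* **Freeman–Halton r×c** — the same probability-mass rule over all tables
  with the observed margins, enumerated recursively.  Probability ties are
  resolved with a relative tolerance of 1e-7 so enumeration order cannot
  change the p-value.  A loose product bound on the enumeration size guards
  the combinatorics; above it the test falls back (on request) to seeded
  Monte-Carlo sampling of margin-fixed tables with the add-one estimator.
  This test is implemented here because no installed Python package
  provides it; it is validated in the tests against exact rational-
  arithmetic enumeration and against values frozen from an independent R
  run.
* **χ²** — Pearson without continuity correction by default; Yates is a
  flag.  The clinical-association engine's default policy is Fisher for
  2×2 tables and χ² for larger ones, which is also the combination that
  reproduces the published p-values the acceptance suite checks.  The
  engine records which test was applied per variable.
* **Mann–Whitney** — exact by enumeration for combined n ≤ 12 without ties;
  normal approximation with tie correction otherwise.
* **Spearman** — mid-ranks for ties; exact p by full permutation
  enumeration for n ≤ 9, t approximation above.
* **BH FDR** — step-up with the monotone envelope, input order preserved.
  Default significance threshold 0.1; the mRNA analysis uses a stricter
  0.01 because of the much larger family.  Families: all tested SNV genes
  form one family; each CNA event class is its own family (classes are
  reported separately and never pooled).
* **Box–Cox regression** — λ by profile maximum likelihood on the pooled
  outcome (scipy's `boxcox_normmax` optimizer; same estimand as a grid
  search, with better-tested numerics), then OLS of the transformed outcome
  on the group indicator plus optional binary covariates, Wald p for the
  group term.  Outcomes with min ≤ 0 are shifted by −min + 1e-6 first (the
  shift is reported).  The effect is additionally reported as the ratio of
  group means on the original scale with a delta-method CI on the log
  scale; for outcomes that can be negative (hypoxia scores) this ratio is
  undefined and reported as NaN while the transformed-scale coefficient and
  p remain valid.

## Differential analyses

A patient with several qualifying variants in one gene counts once for that
gene's 2×2 table — the tested property is "gene mutated in the patient".
The processing order for SNVs is: drop synonymous records (MAF
classification "Silent"), drop excluded genes (TTN by default, a
passenger-mutation magnet), apply the ≥10-patients-in-either-arm filter,
then test and BH-correct — so the BH family contains exactly the tested
genes.

CNA×mRNA integration keeps genes with CNA q < 0.1, mRNA q < 0.01 and
|log2FC| ≥ 1.  A gene significant as both a deletion-type and a gain-type
event is assigned the class with the lower CNA q; the concordant flag marks
gain-with-up or deletion-with-down direction agreement.  Genes lacking a DE
entry are dropped and counted.

## Survival

Kaplan–Meier product-limit with censored subjects counted at risk at their
censoring time; log-rank with df = groups − 1; Cox partial likelihood with
Efron tie handling (ties are common in day-resolution data; fixed, not an
option, for reproducibility) via lifelines.  The median-dichotomized screen
sends exact-median values to the low group, so for odd n the high group has
⌊n/2⌋ members.  Only one event column is modeled; a different endpoint
(e.g. disease-free survival) is the same code path with a different column.

## Synthetic cohort generator

The generator's defaults are the study conditions the analyses assume:

* **Cohort**: n = 496, 15% HPV-positive.
* **Deletion fractions**: per-stratum three-component Beta mixtures.
  HPV-negative: preserved Beta(1, 300) with weight 0.20, lost Beta(350, 6)
  with weight 0.68, intermediate Beta(2, 2) with weight 0.12 — chosen to
  reproduce the observed ≈ 69/19/11% lost/preserved/excluded split of an
  HPV-negative cohort.  HPV-positive: broader lost mode Beta(6, 3) with
  weight 0.38, preserved 0.55, intermediate 0.07.  Homozygous whole-arm
  events at probability 0.008 (≈ 4/496).
* **Spatial structure**: each deletion is one contiguous block of the
  ordered arm gene list (segmental loss).  This is what makes the
  fragile-site and threshold definitions concordant — random gene subsets
  would decouple them.  The recorded true fraction is the realized block
  fraction, and the true status applies the stratum's threshold policy to
  it, so classifier-recovery tests measure the pipeline, not rounding.
  Background aberrations are placed only on arms other than 3p/3q so the
  planted fractions stay exact; their rate is status-dependent (0.05 lost
  vs 0.02 preserved), producing the PGA contrast.
* **3q coupling**: gain probability 0.85 given 3p lost vs 0.15 otherwise
  (isochromosome-3q-like), with occasional amplified sub-blocks.
* **Clinical covariates**: logistic models on true status.  Baselines are
  the arm-preserved proportions of the published cohorts and the log-odds
  effects reproduce the printed directions (e.g. male +1.1, advanced N
  +1.0, stage IV +0.57, distant metastasis +2.3 in HPV-negative disease).
  `ClinicalModel.null()` zeroes every effect for calibration runs.
* **SNVs**: per-gene Bernoulli with status multipliers — a TP53-like
  enriched gene (0.55 base, ×1.6 in lost), CASP8/HRAS/HLA-like depleted
  genes (×0.25–0.35), TTN high-rate and status-neutral, plus 100 background
  genes with rates U(0.01, 0.08); silent records are added alongside 25% of
  hits.
* **Expression**: per-gene log2 baseline N(5, 1.5²), cis dosage effect of
  1.0 log2 units per copy-number step (one step ≈ twofold), hypoxia
  signature genes shifted +1.0 log2 in lost samples, T-cell markers −0.9,
  CAF markers +0.7, Gaussian noise sd 0.8.  Gene sets are drawn
  independently from the non-chr3 pool and may overlap, as real published
  signatures do.  The DE table is computed from the simulated matrix by
  per-gene Welch tests on log2 abundance with BH correction — its q-values
  are calibrated because the null genes really are null.
* **Proteins / miRNAs**: proteins are linear in their gene's log2 mRNA
  (slope 0.8, noise 0.8 ⇒ positive rank correlation); five miRNA–target
  pairs are planted with negative dependence (slope −1, noise 1.7 ⇒
  Spearman ≈ −0.5) and two miRNAs get a +0.8 log2 shift in lost samples.
* **Survival**: exponential baseline hazard 6.4e-4/day (median ≈ 3 years),
  uniform censoring on (1, 2500] days, arm-status hazard ratio **1.0 by
  default** — the null is the default condition, so log-rank calibration is
  exactly checkable; a non-null HR is one config field.

One `numpy` Generator seeded from the config drives everything, with a fixed
draw order (per-sample CNA+clinical, then SNVs, then omics), so a fixed seed
reproduces the bundle byte-for-byte.

What the generator does **not** emulate: real gene symbols beyond a handful
of named markers, allele-specific copy number, tumor purity/ploidy,
batch effects, overdispersed counts (expression is log-normal, not negative
binomial), or informative censoring.  Passing tests therefore demonstrate
correctness of the machinery and calibration under the stated model, not
performance on real TCGA-like data.

## Problem sizes and test design

The test and acceptance runs use desk-scale sizes chosen as the package's
own verification budget: 1,000 random tables with N ≤ 40 for the exact-test
oracles, 1,000 random vectors for BH, a 1,000-sample bundle for classifier
recovery and definition concordance (thresholds ≥ 99% and ≥ 90%), 500
replicates of n = 400 for log-rank type-I error at α = 0.05 (binomial 99%
bounds), and 200 replicates of n = 1,000 for Cox Wald 95% coverage.  Exact
enumeration oracles in the tests use rational arithmetic and bracket the
implementation's tie tolerance from both sides, so floating-point tie
resolution cannot produce flaky comparisons.

## Known limitations

* The Freeman–Halton enumeration is exponential in table size; large sparse
  tables need the Monte-Carlo path.
* The fragile-site gene list of the original microarray method is not
  bundled; the 3p14.2 annotation stand-in must be overridden to replicate
  that method exactly.
* Cox fits inherit lifelines' convergence behavior; separation (e.g. a
  group with no events) surfaces as a recorded error, not a penalized fit.
* Clinical effect magnitudes in the generator reproduce the direction and
  rough size of published proportions, not fitted effect estimates.
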