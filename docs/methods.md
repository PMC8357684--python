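# Methods

## The question and the model

Two tumour groups (a *test* group, e.g. BRCA1-associated or basal-like, and
a *reference* group, e.g. BRCAx or non-basal) are compared not by mean
expression but by the *spread* of expression across samples. Two levels of
analysis are implemented.

**Transcriptome-wide ("equity") regression.** For each gene g and group,
compute a summary statistic s_g: sample SD (n−1 denominator), CV (SD/mean),
MAD (median absolute deviation from the median) or mean. Ordinary least
squares of the test group's statistics on the reference group's gives a
slope β. Under the *equity model* — identical variability in both groups —
β = 1; the reported effect is the percent change (β − 1) × 100, positive
when the test group is more variable. The slope CI uses the normal quantile
(gene counts in the thousands make the t correction irrelevant), and the
equity test is a two-sided Wald test of β = 1. A degree-2 polynomial fit of
the same pairs is reported purely as a linearity diagnostic and is never
used downstream.

Orientation is a convention, declared and recorded in every output: the
test group is the response and the reference group the predictor, so a
positive percent change reads "the test group is X% more variable". The
intercept is included by default (a through-origin option exists) — the two
choices answer slightly different questions and neither is privileged by
the underlying science.

**Per-gene differential variability (DV).** Spread per group is the MAD, a
robust measure insensitive to the outlying intensities that inflate SDs.
Groups are compared by the Brown–Forsythe test: each observation is
replaced by |x − median(its group)| and a one-way ANOVA F statistic is
formed on those deviations, with the upper tail of F(k−1, N−k) as p-value.
The test is location-free (invariant to adding a constant to any group) and
for two groups F equals the square of the pooled t statistic on the
absolute deviations. p-values are Benjamini–Hochberg adjusted across all
genes tested *in one dataset/comparison* — never pooled across datasets —
and a gene is called DV at adjusted p < 0.05 (the conventional FDR level;
it also matches the published consensus tables this pipeline mirrors, whose
adjusted p-values all fall below 0.05). Effect size is the MAD ratio
MAD(test)/MAD(reference), > 1 meaning more variable in the test group.

**Consensus and candidates.** Significant genes are intersected across
datasets, requiring the *same direction* everywhere; genes significant
everywhere but with conflicting directions are counted and excluded. The
top fraction q (default 1.5%) of genes per dataset, ranked by raw p with
ties broken by |log MAD ratio| then gene id, gives ceil(q·m) genes whose
cross-dataset and cross-analysis intersections are the replicated
candidates. Raw p is used for ranking because BH adjustment is monotone
within a dataset (the selected set is identical) but creates plateau ties.

**Regulator enrichment.** A DV gene set is tested against each ChIP-derived
target set of a GMT collection with a two-sided Fisher exact test on the
2×2 table (DV vs control = universe ∖ DV) × (in set vs not), membership
restricted to the universe of genes actually analysed in the DV comparison.
The odds ratio gets the Haldane–Anscombe +0.5 correction only when a cell
is zero (so log OR stays finite); the p-value is always the uncorrected
exact one. Set-level results aggregate to regulators by a two-sided
Wilcoxon rank-sum test of each regulator's log-OR values against all other
sets, ranked by p then median log OR; single-set regulators are flagged
low-evidence.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| MAD scale constant | 1.0 | 1.4826 gives Normal-consistent scale; every ratio and slope is invariant to it |
| DV significance α | 0.05 | on BH-adjusted p, per dataset |
| top fraction q | 0.015 | candidate ranking depth per dataset |
| CI level | 0.95 | slopes and MAD ratios |
| bootstrap B | 2000 | MAD-ratio CI replicates |
| polynomial degree | 2 | linearity diagnostic only |

Medians use the midpoint convention for even n. CV is computed on the
analysis (log2) scale and left undefined (NaN, excluded pairwise with a
reported count) where the group mean is ≤ 0. Matrices are assumed already
log2-scaled; readers offer a log2(x + offset) transform (default offset 1)
for raw-scale input. Missing values are rejected, not imputed: none of the
statistics here defines a missing-data policy, and silent imputation would
change spreads.

## MAD-ratio confidence intervals

The interval construction for a ratio of MADs is genuinely open; three are
offered. The default is a **stratified BCa bootstrap** (each group
resampled independently, B = 2000, seeded): the bootstrap distribution of a
MAD ratio at cohort-sized n (tens of samples) is lumpy, skewed and
heavy-tailed, and the plain percentile interval overcovers badly (measured
~0.99 at nominal 0.95 for two Normal groups of 50), while BCa's bias and
acceleration corrections restore close-to-nominal coverage (measured 0.941
over 1500 null replicates). The plain **percentile** interval and a
**normal-theory log-scale** interval — Var(log MAD) ≈ 1.361/n per group,
from the MAD's ~37% efficiency relative to the SD under normality — remain
as options. In the per-gene pipeline each gene receives an independent
child seed spawned from the run seed, so the full table is reproducible
from one integer. Intervals are clipped to contain the point estimate.

## Degenerate inputs and tie-breaks

* A gene constant in both groups (all deviations zero) is *degenerate*:
  reported with F = 0, p = 1, direction "0", and **kept** in the BH
  universe — dropping it would silently change the multiplicity m.
* Zero reference MAD with non-zero test MAD: ratio undefined (scalar API
  raises; the pipeline flags the record, reports an infinite ratio with NaN
  CI, and keeps the Brown–Forsythe p, which is still valid).
* Zero test MAD: ratio 0 with a warning flag.
* Quantile normalization averages tied values over the rank-means their
  positions span, making it deterministic and invariant to row permutation,
  and idempotent.
* An empty cross-dataset consensus is a valid result, not an error.

## The synthetic cohort generator

`simulate_cohort` emulates a quantile-normalized two-group microarray
cohort on the log2 scale. Per gene: baseline mean μ_g ~ Normal(7.5, 3.0)
(arrays span roughly 2–14 log2 units across genes) and baseline SD
σ_g ~ LogNormal(meanlog −1.9, sdlog 0.7) (median per-gene spread ≈ 0.15
with the long right tail real per-gene SD distributions show). Reference
samples are Normal(μ_g, σ_g); test samples Normal(μ_g, σ_g·λ·ρ_g), with λ a
transcriptome-wide inflation shared by all genes (default 1.25) and ρ_g an
extra inflation (default 3) applied only to a planted fraction f (default
10%) of genes. Group means are identical by construction, isolating
variability effects. One seeded generator drives all draws in a fixed
order (means, SDs, planted choice, reference matrix, test matrix), so data
and ground truth co-reproduce bit-identically. Defaults (2000 genes, 50+50
samples) run the full pipeline in well under a minute.

What the generator deliberately does **not** emulate: probe-level artefacts,
batch effects, mean–variance coupling, heavy-tailed intensity noise,
copy-number-driven expression, or correlation between genes. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under a clean model, not robustness to every real-microarray
pathology; the robust (median-based) spread statistics are chosen precisely
because they tolerate such pathologies.

## Errors-in-variables attenuation

The equity regression's predictor is an *estimated* statistic, so the
fitted slope is attenuated toward zero by the classical errors-in-variables
factor — for SD statistics, approximately
Var(σ)/(Var(σ) + E[σ²]/(2n)) with n the per-group sample size. Under the
generator defaults this is ≈0.987 at n = 100, so a true λ = 1.30 yields an
expected slope ≈1.284, and even a λ = 1 null cohort gives a slope ≈0.987
whose tight CI (thousands of genes) sits *below* 1. This is documented and
not corrected, mirroring the plain-OLS design of the analysis it
implements; tests assert slope recovery within attenuation-sized bands
rather than exact CI coverage of the truth. Mean statistics are essentially
unattenuated (across-gene mean variance dwarfs the standard error of a
mean), which is why the mean-equity CI does cover 1.

A related calibration fact: the median-centred Brown–Forsythe test is
mildly conservative at moderate sample sizes — its measured type-I error at
α = 0.05 with two Normal groups of 30 is ≈0.041 (20,000 null genes),
converging to the nominal level as n grows (≈0.045 at n = 50, ≈0.048 at
n = 100). Conservatism costs a little power but never inflates the FDR.

## Problem sizes used in validation

The test suite and acceptance script run at sizes chosen to make
Monte-Carlo error small relative to the effects checked: 10,000 null gene
pairs for type-I calibration; 10,000 genes × 100 samples/group for
inflation recovery; 20 cohorts of 2000 genes × 50/group for FDR and power;
1000 replicates for CI coverage. DV-calling operating characteristics are
computed without per-gene bootstrap CIs (the CI method cannot change a
p-value), keeping those runs to seconds.

## Known limitations

* No meta-analytic pooling of evidence across datasets — consensus is by
  intersection, which is conservative and sensitive to each dataset's
  power.
* No covariate adjustment (e.g. ER status), batch correction, or
  probe-to-gene collapsing; inputs are assumed pre-assembled, normalized
  matrices.
* The regulator aggregation is one reasonable rank-based summary among
  several; with few sets per regulator its p-values are coarse.
* OLS equity slopes inherit the attenuation described above; an
  errors-in-variables correction is intentionally out of scope.
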