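# Methods

This note documents the statistical model behind each `seedcoex` stage, the
default parameters and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## 1. Seed-gene co-expression

**Correlation.** For each non-seed probe, Pearson r against the seed's
reference probe (the probe with the largest sample variance among probes
mapping to the seed symbol; ties break to the lexicographically smallest
probe id). Missing values are handled pairwise-complete; a probe needs at
least `min_samples = 10` complete pairs (below that, correlation estimates
are too unstable to rank). The two-sided p-value uses the exact transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, which is the exact null
distribution under bivariate normality and a good approximation otherwise.

**Filter.** A gene enters a seed's module when |r| > `r_cutoff` (default
0.3) **and** p < `alpha` (default 0.05), both strict. 0.3 is the
conventional "moderate correlation" floor for co-expression screens on
cohorts of ~100 samples, where it corresponds to p ≈ 0.0025 — so the |r|
condition, not the p condition, is usually binding, and the filter targets
effect size rather than bare significance. Genes are partitioned by the
sign of r into positive and negative sub-modules.

**Probe deduplication.** One row per gene symbol: the probe with the
smallest p; ties break to the larger |r|, then the smallest probe id.
Choosing the most significant probe (rather than averaging) mirrors how
array studies report per-gene results and keeps the chosen statistic
directly traceable to one measured probe. Probes without a symbol pass
through unchanged; symbols whose every probe failed correlation keep one
flagged placeholder row.

**Intersection.** The common set of two seed modules ignores correlation
sign (a gene may couple positively to one factor and negatively to the
other); per-gene sign concordance is reported, not imposed.

## 2. Enrichment

**Over-representation.** Hypergeometric upper tail P(X ≥ k) computed in
log space via the survival function, with universe = all annotated symbols
on the platform after deduplication. Terms are restricted to the universe
and skipped outside 5–2000 members (below 5 the test is uninformative;
above 2000 terms are too generic to interpret). Benjamini–Hochberg step-up
is applied separately within each gene-set family (KEGG, GO-BP, …), since
families are separate hypothesis batches with very different sizes. The
BH implementation is the hand-written step-up
min_{j≥i}(m·p_(j)/j), validated against `statsmodels` in the tests.

**Preranked GSEA.** Weighted Kolmogorov–Smirnov running sum (hit increments
∝ |score|^w with w = 1, miss increments 1/(N−m)), enrichment score = the
extremum of the running sum, evaluated only at hit-adjacent positions
(the extremum of a piecewise-linear path with negative drift between hits
can only occur there, making the scan O(m) per permutation). The null is
gene-label permutation. The permutation p-value is
(1 + #{same-sign permuted ES at least as extreme}) / (1 + #{same-sign
permuted ES}): conditioning on the sign is required because the observed
ES is compared only against excursions in its own direction — using all
permutations in the denominator would roughly double the null rejection
rate. NES = ES / mean |same-sign permuted ES|. Default `n_perm = 1000`
gives p resolution ~10⁻³; the permutation stream is seeded (`gsea_seed`)
for exact reproducibility.

## 3. Candidate follow-up

**Auto-selection.** When `candidate = "auto"`, common genes are ranked by
the standardized mean expression difference between the target subgroups
(default ST-RELA+ and PF-A, the aggressive ependymoma subgroups) and all
other samples; the full ranking is written out so the choice is auditable.

**Signature correlations.** Each signature gene is collapsed to its most
significant probe (same rule as module deduplication) and classified
positive / negative / none against the candidate at p < 0.05; fractions
are over matched genes only, and unmatched genes are listed, never
silently absorbed into a denominator.

**Group tests.** Welch (unequal-variance) t-test for two groups, one-way
ANOVA for more. Groups are ordered by sorted label so the sign of the
statistic is deterministic.

**ΔΔCt.** ΔCt = target Ct − arithmetic mean of the ACTB and GAPDH Cts
(equivalent to geometric-mean normalization of the linear quantities,
the standard two-housekeeper scheme). ΔΔCt subtracts the calibrator
group's mean ΔCt per target; fold change = 2^−ΔΔCt. By construction the
calibrator group has **geometric** mean fold change exactly 1 (its
arithmetic mean exceeds 1 whenever there is any spread, by Jensen's
inequality — a common source of confusion when reading fold-change
tables).

## 4. Survival

Expression is dichotomized at the median (high = strictly above; at least
4 samples and a non-degenerate split required). Kaplan–Meier curves and
the two-group log-rank test are delegated to `lifelines`. The univariate
Cox model is fit by Newton iteration on the Breslow partial likelihood
(ties handled by Breslow's approximation; convergence when |score| < 1e−8,
up to 50 iterations, steps clipped to ±2; |β| > 20 is flagged as monotone
likelihood / non-convergence rather than reported as a finite hazard
ratio). The Cox score test at β = 0 equals the log-rank chi-square exactly
on untied data, which the tests verify to 1e−6 as a cross-implementation
consistency check; the fit itself is validated against a brute-force
partial-likelihood grid search and against `lifelines.CoxPHFitter`.

## 5. Synthetic generator

**Model.** Latent-factor planting: each seed gene is a standard normal
factor f; a gene targeted at correlation ρ is drawn as
g = sign·ρ·f + √(1−ρ²)·ε, so its population correlation with the seed is
exactly sign·ρ. Overlap genes use ρf₁ + ρf₂ with residual variance
1 − 2ρ², giving correlation ρ to each seed. Latent z-scores are shifted to
a log2-like scale by per-gene means drawn uniformly from [5, 9].

**Defaults (the study conditions).**

- `n_samples = 100`, `n_background = 960`: a typical single-platform
  cohort; ~1000 genes keeps the false-positive accounting meaningful while
  the suite stays fast.
- Per-seed blocks of 24 positive + 16 negative genes at ρ = 0.6: at
  n = 100 this puts planted genes ~5 SE above the 0.3 cutoff, so recovery
  is a sensitivity measurement, not a coin flip.
- `overlap_size = 30` at ρ = 0.6 to both seeds; the candidate (IL1R1)
  occupies one overlap slot at ρ = (0.489, 0.579). Those values are chosen
  so that **after** the candidate's +1.0 subgroup shift (which inflates
  its marginal variance by 0.52·0.48 ≈ 0.25 and so dilutes correlations by
  1/√1.25) its observed correlations with the seeds sit near 0.44 and
  0.52 — moderate, realistic effect sizes rather than saturated ones.
- Subgroup proportions ST-RELA+ 0.16, ST-RELA− 0.14, PF-A 0.36, PF-B 0.20,
  SP 0.14: loosely the site mix of published ependymoma cohorts
  (supratentorial ~30%, posterior fossa ~55%, spinal ~15%).
- `duplication_rate = 0.10`: each gene gains a second, noisier probe
  (`_s_at` suffix, extra N(0, 0.3²) noise) with probability 0.1, exercising
  the deduplication rule under realistic conditions.
- Gene sets: 4 planted terms of size 30 drawing 80% of members from the
  planted blocks, 20 size-matched null terms, split across two families.
- Signature: 61 genes, 44 positive (ρ = 0.5), 4 negative (ρ = −0.4),
  13 uncorrelated with the candidate — the class mix of a published EMT
  signature screen.
- Survival: exponential event times at baseline hazard 0.02/month,
  multiplied by exp(log 4.37) for candidate-high samples; independent
  exponential censoring at 0.01/month plus administrative censoring at
  120 months. log(4.37) is a large but realistic prognostic effect for a
  dichotomized biomarker.
- qPCR: Ct = 40 − expression + N(0, 0.2²); housekeepers ACTB/GAPDH at
  Ct 18/19 with N(0, 0.15²) noise. One cycle per log2 expression unit is
  the ideal-efficiency assumption of the comparative-Ct method.

**Randomness.** All draws derive from one master seed through named
`numpy.random.SeedSequence` child streams (expression, duplication,
gene_sets, survival, qpcr), so regeneration is bit-identical and adding
draws to one component never perturbs another.

**What the generator emulates:** correlation block structure with exact
population targets, probe multiplicity, subgroup-specific expression
shifts, set enrichment inside modules, signature class structure,
proportional-hazards survival tied to a marker, and Ct values linear in
expression.

**What it does not emulate:** array normalization artifacts, batch
effects, heavy-tailed or count-based noise, correlated background
(background genes are iid), gene–gene structure beyond the planted
factors, non-proportional hazards, informative censoring, competing
risks, or qPCR efficiency differences between targets. Conclusions about
robustness to those phenomena cannot be drawn from this generator.

## 6. Pipeline determinism

Stage outputs are plain TSV written with repr-level float formatting; the
run manifest records the module-size funnel, seeds and a SHA-256
configuration hash (excluding `out_dir`, since where a bundle lands does
not change what was computed). An `INCOMPLETE` marker exists while a run
is in progress and is removed only on success; stage failures raise
`StageError` naming the stage. Byte-identical reruns under identical
configuration are asserted by the test suite.

## 7. Limitations

- The correlation filter is marginal (one gene at a time): it has no
  notion of conditional independence and will pass genes correlated with a
  seed only through a confounder.
- BH control is per family and assumes the usual positive-dependence
  conditions; p-values entering it come from marginal tests on the same
  data used to form the modules.
- Median dichotomization discards information and the resulting hazard
  ratio depends on the cohort's expression distribution; it is used here
  because it is the field's convention, not because it is efficient.
- The univariate Cox model fits a single binary covariate; no adjustment
  for subgroup, age or other prognostic factors is performed.
- Permutation GSEA p-values are limited to resolution 1/(n_perm+1) and are
  conservative by construction.
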