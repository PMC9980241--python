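# Methods

This note documents the statistical procedures the package implements, the
defaults it chooses where the design was genuinely open, and what the
synthetic-data engine does and does not emulate.

## Harmonization

Scoring files are matched to the target panel by chromosome:position and
the unordered allele pair; weights are re-expressed per copy of the panel's
*alternative* allele, so a record whose effect allele equals the panel
reference has its weight negated. Records that cannot be matched are
excluded and counted, never silently altered:

* positions absent from the panel, or allele pairs matching neither panel
  orientation (including multi-allelic leftovers and build mismatches);
* strand-ambiguous palindromic pairs (A/T, C/G), dropped by default because
  strand cannot be resolved without allele-frequency inference, which is out
  of scope; `keep_ambiguous=True` retains them under a same-strand
  assumption;
* rsID-only records without an entry in a user-supplied rsID→position map.

Duplicate variant identifiers within one file are a hard error — they
usually indicate upstream file corruption, and summing them silently would
double weights. Positions are 1-based throughout (PGS Catalog convention).

## Scoring

PRS values are plain dosage–weight sums over the variants shared between a
harmonized score and the genotype matrix. Missing dosages are imputed as
2·p̂, with p̂ the alt-allele frequency among non-missing entries of the same
variant — the convention of standard scoring tools. Raw scores are never
standardized at computation time; standardization happens once, inside the
mixer, with training-split statistics, so stored score tables are
reproducible and splitting-independent.

## Accuracy, power, and score selection

* **Partial R²** is R²(full) − R²(null) from least-squares fits with and
  without the score, covariates in both; its p-value is the 1-df nested
  F comparison. For binary traits the observed-scale partial R² comes from
  least squares on the 0/1 outcome (linear probability model) — the scale on
  which the liability transformation is defined; logistic pseudo-R² is
  deliberately not used. The binary p-value is the Wald test on the score in
  a covariate-adjusted logistic model.
* **Liability R²** multiplies the observed-scale R² by
  K²(1−K)²/(z²·P(1−P)), z the standard normal density at the K-quantile,
  P the sample case proportion, K the population prevalence. With K set to
  the sample prevalence (the package default, matching the cohort-internal
  convention) this reduces to K(1−K)/z², which equals π/2 at K = 0.5. The
  two-prevalence form is exposed for users who know the population K.
* **Power** of the score–trait association uses the non-centrality parameter
  λ = N·R²/(1−R²) in the two-sided normal approximation
  1 − Φ(z₁₋α/₂ − √λ) + Φ(zα/₂ − √λ); the equivalent non-central χ²₁ form is
  provided as a cross-check (they agree to ~1e−3). Both forms are validated
  against Monte-Carlo rejection rates in the test suite.
* **se(R²)** uses the classical asymptotic variance
  4R²(1−R²)²(N−2)²/((N²−1)(N+3)), validated against the empirical SD of R̂²
  over simulated fits.
* **Selection** retains scores with power > 0.95 and association p ≤ 0.05
  (both configurable; a Bonferroni-style p-threshold such as 0.05/2600 can
  be supplied instead — filtering is monotone in the threshold, so the
  stricter choice only shrinks the retained set). Degenerate R² = 1 fits are
  capped for the λ/power/se computations rather than erroring.

## The mixing model

Candidate scores on the training split (default 80%, stratified on case
status for binary traits, all randomness from one seed) are standardized to
mean 0, variance 1. The combination is an elastic net — L1 ratio 0.5 by
default, penalty strength chosen at minimum 5-fold cross-validated loss —
with covariates and intercept unpenalized.

* Continuous family: the unpenalized covariate block is concentrated out
  exactly by the Frisch–Waugh device (the joint minimizer of squared error
  plus a penalty on score coefficients only equals the elastic net on
  covariate-residualized outcome and scores), and `ElasticNetCV` fits the
  residualized problem; covariate coefficients are recovered by least
  squares afterwards.
* Binary family: a penalized logistic fit with a per-coefficient penalty
  vector (zero on intercept and covariates), run over a glmnet-style
  geometric lambda path (15 values spanning two decades below the null-model
  gradient bound) with stratified 5-fold CV on held-out deviance and warm
  starts along the path.

Mixing weights are reported on both scales: ω̂ᵢ (standardized) and
α̂ᵢ = ω̂ᵢ/σᵢ (raw), with the training SDs σᵢ. Per-variant combined effects
γ̂ⱼ = Σᵢ α̂ᵢβⱼᵢ are formed over the union of variants with absent entries
contributing zero; the intercept only shifts the score's location and is
discarded. The identity "scoring the derived file = Σᵢ α̂ᵢ·PRSᵢ" is exact up
to float roundoff and asserted in the tests at 1e−8.

If cross-validation selects the all-zero score model the result is flagged
non-informative (`MixWeights.informative`), and the pipeline reports no
combined-score accuracy rather than silently falling back to the best single
score. The best-single baseline is always chosen on the training split and
evaluated on the test split, like the combination itself.

PRSmix restricts candidates to scores whose trait label equals the outcome
label after case normalization; PRSmix+ admits every high-power score,
including the outcome trait's own (a superset of PRSmix's input). With only
outcome-trait scores present the two coincide by construction.

## Clinical utility

* **Category-free NRI** = P(up|case) − P(down|case) + P(down|control) −
  P(up|control), where up/down are *strict* probability movements — ties
  count as neither, and the tie count is reported so that degenerate model
  pairs are visible. CI: percentile bootstrap, 500 replicates by default.
* **Incremental AUC** = AUC(augmented) − AUC(baseline), AUC by the rank
  (Mann–Whitney) formulation with ties counted ½, same bootstrap. An
  analytic DeLong-style CI is deliberately out of scope, keeping the two
  metrics' uncertainty treatment uniform.
* **Odds ratios** come from covariate-adjusted logistic fits: per 1 SD of
  the score (standardized over the evaluation sample), and for the top
  decile versus the rest (90th percentile from the evaluation sample
  itself; ties at the threshold stay in the reference group). Separation is
  raised as a diagnostic error instead of returning unbounded estimates.
* **Association scan**: one covariate-adjusted logistic fit per binary
  phenotype column, significance at alpha divided by the number of columns
  actually tested (single-class columns are skipped with a warning and do
  not consume multiplicity).

## Simulation engine

What it emulates: M unlinked causal variants in Hardy–Weinberg equilibrium
with MAF ~ U(0.01, 0.5); per-score SNP effects from MVN(0, Σ) with diagonal
h²/M and off-diagonals r_g·h²/M (r_g = 0.8 within the trait-specific block
of 3 scores, 0.4 elsewhere — the cross-trait block of 3); an outcome genetic
component g combining all component scores with U(0,1) weights drawn once
per replicate and recorded; y = g + e with e ~ N(0, 1−h²).

Two deliberate numerical choices:

* **g is rescaled to variance exactly h²** after combining components —
  with finite M and realized genotypes the raw combination's variance
  deviates from h², and the residual law N(0, 1−h²) only produces a
  unit-variance phenotype when var(g) = h² holds exactly.
* **Component scores are estimated, not true**: each component trait gets
  its own phenotype (variance-h² genetic part plus noise) on a disjoint GWAS
  sample, a marginal per-SNP regression estimates weights, and those noisy
  estimates — not the true β — form the single PRSs entering the mixer.
  This reproduces the attenuation of single-score accuracy with small GWAS
  samples without needing LD-aware machinery.

What it does not emulate: linkage disequilibrium (variants are independent,
so no tagging or clumping behavior), ancestry structure and relatedness,
genotyping error and imputation uncertainty, and biobank-scale sample sizes.
Passing sweeps therefore demonstrate the *combination machinery* — that
mixing recovers more test-set R² than the best single score and that the
gain grows with training size, fastest for low-heritability traits — not
cohort-level effect sizes, which depend on real LD and score redundancy
structure.

The training-size sweep allocates GWAS, training-pool, and test samples
disjointly within each replicate, feeds all component scores into the fit
(the filter stage is for heterogeneous published panels; here every
component carries signal by construction), and aggregates fold-ratios per
(h², n_train) cell; the improvement slope is the least-squares slope of the
cell-mean fold-ratio on log10(n_train). Shipped configurations are
desk-scale (default grid: M = 200, GWAS n = 5,000, n_train ∈ {250, 1000,
4000}, n_test = 1,500, 20 replicates, h² ∈ {0.1, 0.5}); at h² = 0.5 this
grid already saturates mixing-weight training at its smallest point, so the
slope is informative mainly at the low-heritability level. The replicate
count and problem sizes were chosen once as the smallest design in which
the Monte-Carlo error of the cell means is comfortably below the effects of
interest.

## Known limitations

* Mixing weights are trained and evaluated within one cohort split; no
  external-cohort transfer of α̂ is attempted.
* The elastic net assumes an additive, linear relationship between
  component scores and outcome.
* Binary-trait penalized fitting uses an in-package lambda path and CV loop;
  its selected penalty can differ from glmnet's default path in edge cases,
  though both select by minimum CV deviance.
* Frequency-based strand resolution, liftover, and live PGS Catalog access
  are out of scope; inputs must share a genome build.
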