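# prsmix

**prsmix** combines many published polygenic scores (PRS) for the same
individual into a single, more accurate score. Thousands of per-variant
weight files are available in PGS Catalog format, often dozens per trait and
of very uneven quality; rather than picking one, this package harmonizes
them against a genotype panel, filters them analytically by the power of
their trait association, and learns an elastic-net linear combination:

* **PRSmix** — combine the scores developed for the *outcome trait* itself;
* **PRSmix+** — additionally admit high-power scores from *other traits*,
  exploiting pleiotropy (genetically correlated traits carry independent
  signal for the outcome).

It is aimed at statistical geneticists and biobank analysts who have
individual-level dosages, phenotypes, and a directory of scoring files.

## The model

For individual *n*, each component score is the weighted allele count
PRSᵢₙ = Σⱼ βⱼᵢ·dosageₙⱼ after harmonizing every effect allele to the panel's
alternative allele. On an 80% training split, scores are standardized
(mean 0, variance 1) and an elastic net with 5-fold cross-validation and
unpenalized covariates (age, sex, 10 PCs) estimates mixing weights ω̂ᵢ.
These are returned to the raw-score scale, α̂ᵢ = ω̂ᵢ/σᵢ, and pushed down to
per-variant effects of the combined score

γ̂ⱼ = Σᵢ α̂ᵢ βⱼᵢ  (βⱼᵢ = 0 if variant *j* is absent from score *i*),

which write out as an ordinary scoring file usable by any PRS calculator.

Candidate scores are pre-filtered on the training split by the power of the
two-tailed association test, computed from the non-centrality parameter
λ = N·R²/(1−R²): retain scores with power > 0.95 and p ≤ 0.05. Accuracy is
partial R² (continuous traits) or liability-scale R² (binary traits,
converted with the prevalence factor K(1−K)/z²). Evaluation on the held-out
20% compares the combination against the best single score chosen on the
training split — the **fold-ratio** of their R² is the improvement metric —
and clinical utility is summarized by category-free NRI, incremental AUC,
and odds ratios per SD and for the top decile.

A simulation engine generates the full study synthetically: Hardy–Weinberg
genotypes, per-score SNP effects drawn from MVN(0, Σ) with genetic
correlation 0.8 among trait-specific scores and 0.4 across traits,
phenotypes y = g + e with var(g) = h², and GWAS-estimated component scores,
so that training-size and heritability sweeps run on a desktop.

## Worked example

```python
import numpy as np
from prsmix.simulate import make_demo_study
from prsmix.scoring import build_panel
from prsmix.prs_stats import SelectionRule
from prsmix.mixer import prsmix, prsmix_plus, SplitSpec

genotypes, scorings, y, covars = make_demo_study(
    n_samples=2000, m=100, n_gwas=4000, h2=0.5, seed=42
)
panel = build_panel(genotypes, scorings)
panel.trait_labels = {s.score_id: s.trait_label for s in scorings}

spec = SplitSpec(train_fraction=0.8, seed=42)
rule = SelectionRule(power_threshold=0.95, p_threshold=0.05)
mix = prsmix(panel, "trait_specific", y, covars, spec, rule, scorings=scorings)
plus = prsmix_plus(panel, y, covars, spec, rule, scorings=scorings)

print(f"retained (PRSmix):   {mix.retained_ids}")
print(f"best single score:   {mix.best_single_id} "
      f"(test R2 = {mix.best_single_test_accuracy.r2:.3f})")
print(f"PRSmix  test R2:     {mix.test_accuracy.r2:.3f}")
print(f"PRSmix+ test R2:     {plus.test_accuracy.r2:.3f}")
print(f"PRSmix+ fold-ratio:  {plus.test_accuracy.r2 / plus.best_single_test_accuracy.r2:.2f}")
print(f"adjusted weights:    {np.round(plus.weights.alpha_adj, 3)}")
```

prints

```
retained (PRSmix):   ['PRS001', 'PRS002', 'PRS003']
best single score:   PRS003 (test R2 = 0.380)
PRSmix  test R2:     0.419
PRSmix+ test R2:     0.463
PRSmix+ fold-ratio:  1.22
adjusted weights:    [0.08  0.391 0.378 0.124 0.163 0.121]
```

The three trait-specific scores pass the power filter; mixing them lifts
the held-out R² from 0.380 (best single) to 0.419, and admitting the three
correlated cross-trait scores lifts it further to 0.463 — a 1.22-fold
improvement. `plus.effects` holds the re-derived per-variant weights γ̂ⱼ,
writable with `prsmix.pgs_io.write_scoring_file` and scoreable like any
published file.

The same workflow is available from the shell:

```bash
prsmix harmonize --scores scores/ --panel panel.tsv --out harmonized/
prsmix score --genotypes dosages.tsv --scores harmonized/ --out scores.tsv
prsmix mix --scores scores.tsv --meta meta.tsv --pheno pheno.tsv \
       --trait height --covars age,sex --seed 42 --out height_mix
```

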