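"""Synthetic-data engine for score-combination experiments.

The generative model mirrors the PRS-level simulation design used to study
score combination:

* Bi-allelic genotypes are drawn in Hardy–Weinberg equilibrium at M causal
  variants with per-variant MAF uniform on a configurable range (default
  0.01–0.5); variants are unlinked (no LD).
* Per-score SNP effects for the component scores are drawn from a
  multivariate normal MVN(0, Σ) with diagonal h²/M and off-diagonal
  r_g·h²/M — r_g = 0.8 within the trait-specific block and 0.4 elsewhere
  (the pleiotropic, cross-trait block).
* The outcome's genetic component g is a U(0,1)-weighted combination of the
  component genetic scores, rescaled so that var(g) = h² exactly, and the
  phenotype is y = g + e with e ~ N(0, 1−h²).
* Component scores are *estimated* via a marginal per-SNP GWAS on a disjoint
  GWAS sample, so the single scores entering the mixer carry realistic
  estimation noise that shrinks with the GWAS sample size.

``sweep_training_sizes`` runs the full pipeline over a grid of training
sample sizes and heritabilities and aggregates fold-ratios of the combined
score's test R² over the best single score's; ``improvement_slope`` regresses
the mean fold-ratio on log10(N) per heritability level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixer import fit_mixture
from .pgs_io import HarmonizedScoring, VariantKey
from .prs_stats import partial_r2
from .scoring import GenotypeMatrix, ScorePanel

__all__ = [
    "SimConfig",
    "SimEffects",
    "PhenotypeDraw",
    "SweepResult",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotype",
    "component_phenotypes",
    "run_gwas",
    "sweep_training_sizes",
    "improvement_slope",
    "make_demo_study",
]


@dataclass
class SimConfig:
    """Parameters of one simulated combination study.

    Defaults follow the reference design: M = 1000 causal SNPs, three
    trait-specific component scores with genetic correlation 0.8, three
    cross-trait components at 0.4, and 200 replicates.
    """

    h2: float = 0.5
    m_causal: int = 1000
    n_scores_specific: int = 3
    n_scores_cross: int = 3
    rg_specific: float = 0.8
    rg_cross: float = 0.4
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_gwas: int = 10_000
    n_train_grid: tuple[int, ...] = (1_000,)
    n_test: int = 2_000
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must lie in (0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for size in (self.m_causal, self.n_gwas, self.n_test, self.n_replicates,
                     *self.n_train_grid):
            if size < 1:
                raise ValueError("all sizes must be >= 1")

    @property
    def n_scores(self) -> int:
        return self.n_scores_specific + self.n_scores_cross

    def effect_correlation(self) -> np.ndarray:
        """Score-score correlation matrix of per-SNP effects."""
        k = self.n_scores
        R = np.full((k, k), self.rg_cross)
        s = self.n_scores_specific
        R[:s, :s] = self.rg_specific
        np.fill_diagonal(R, 1.0)
        return R

    def effect_covariance(self) -> np.ndarray:
        return self.effect_correlation() * (self.h2 / self.m_causal)


@dataclass
class SimEffects:
    """True per-score SNP-effect matrix (m_causal x n_scores)."""

    beta: np.ndarray
    config: SimConfig

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite simulated effect")


@dataclass
class PhenotypeDraw:
    """One simulated outcome: y = g + e with recorded combination weights."""

    y: np.ndarray
    g: np.ndarray
    u: np.ndarray              # U(0,1) weights combining the component scores
    components: np.ndarray     # n x n_scores true genetic component scores


@dataclass
class SweepResult:
    """Fold-ratio grid over (h2, n_train) for PRSmix and PRSmix+."""

    data: pd.DataFrame  # columns: h2, n_train, method, replicate, fold_ratio, r2_combined, r2_best
    config: SimConfig
    h2_grid: tuple[float, ...] = ()

    def summary(self) -> pd.DataFrame:
        """Mean fold-ratio with normal-theory 95% CI per (h2, n_train, method) cell."""
        def agg(group: pd.Series) -> pd.Series:
            m = group.mean()
            se = group.std(ddof=1) / np.sqrt(len(group)) if len(group) > 1 else 0.0
            half = stats.norm.ppf(0.975) * se
            return pd.Series({"mean_fold_ratio": m, "ci_lo": m - half,
                              "ci_hi": m + half, "n_replicates": len(group)})
        return (self.data.groupby(["h2", "n_train", "method"])["fold_ratio"]
                .apply(agg).unstack().reset_index())


def simulate_genotypes(
    n: int, m: int, maf_range: tuple[float, float] = (0.01, 0.5), seed: int = 0
) -> GenotypeMatrix:
    """Unlinked Hardy–Weinberg genotypes with uniform MAF on ``maf_range``."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("invalid maf_range")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    # two independent allele draws per sample: HWE by construction
    dosages = (rng.random((n, m)) < maf).astype(float)
    dosages += (rng.random((n, m)) < maf)
    variants = [VariantKey("1", j + 1, "A", "G") for j in range(m)]
    return GenotypeMatrix(
        sample_ids=[f"S{i:06d}" for i in range(n)],
        variants=variants,
        dosages=dosages,
    )


def simulate_effects(config: SimConfig, rng: np.random.Generator | None = None) -> SimEffects:
    """Draw correlated per-score SNP effects from MVN(0, Σ)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cov = config.effect_covariance()
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1e-300):
        raise ValueError("effect covariance matrix is not positive semi-definite")
    beta = rng.multivariate_normal(
        mean=np.zeros(config.n_scores), cov=cov, size=config.m_causal,
        method="eigh",
    )
    return SimEffects(beta=beta, config=config)


def _centered(genotypes: GenotypeMatrix) -> np.ndarray:
    X = genotypes.dosages
    return X - X.mean(axis=0)


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate genetic component (zero variance)")
    return (x - x.mean()) / sd * np.sqrt(target_var)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    effects: SimEffects,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeDraw:
    """Outcome phenotype y = g + e from a U(0,1)-weighted component mixture.

    The realized g is rescaled to variance exactly h² so that the residual
    law e ~ N(0, 1−h²) yields a unit-variance phenotype.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    components = _centered(genotypes) @ effects.beta
    u = rng.uniform(0.0, 1.0, size=config.n_scores)
    g = _scale_to_var(components @ u, config.h2)
    if config.h2 >= 1.0:
        e = np.zeros(len(g))
    else:
        e = rng.normal(0.0, np.sqrt(1.0 - config.h2), size=len(g))
    return PhenotypeDraw(y=g + e, g=g, u=u, components=components)


def component_phenotypes(
    genotypes: GenotypeMatrix,
    effects: SimEffects,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One trait phenotype per component score (columns), for GWAS input.

    Each component's genetic score is rescaled to variance h² and
    independent N(0, 1−h²) noise is added.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    components = _centered(genotypes) @ effects.beta
    out = np.empty_like(components)
    for i in range(components.shape[1]):
        g = _scale_to_var(components[:, i], config.h2)
        out[:, i] = g + rng.normal(0.0, np.sqrt(1.0 - config.h2), size=len(g))
    return out


def run_gwas(genotypes: GenotypeMatrix, phenotype: Sequence[float]) -> pd.DataFrame:
    """Marginal per-SNP least-squares regression of phenotype on centered dosage.

    Returns one row per variant with ``beta``, ``se`` and ``p``; monomorphic
    variants get NaN estimates.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n <= 3:
        raise ValueError("GWAS requires n > 3")
    X = _centered(genotypes)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", X, X)
    sxy = X.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / np.where(sxx > 0, sxx, np.nan))
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return pd.DataFrame({
        "variant": [str(k) for k in genotypes.variants],
        "beta": beta, "se": se, "p": p,
    })


def _replicate_fold_ratios(
    config: SimConfig, h2: float, replicate: int
) -> list[dict]:
    """One simulation replicate: GWAS, single-score building, mixing, testing."""
    cfg = replace(config, h2=h2)
    ss = np.random.SeedSequence([int(config.seed) % (2**31), int(round(h2 * 1000)), replicate])
    child = ss.generate_state(4)
    rng = np.random.default_rng(child[0])

    max_train = max(cfg.n_train_grid)
    n_total = cfg.n_gwas + max_train + cfg.n_test
    genotypes = simulate_genotypes(
        n_total, cfg.m_causal, cfg.maf_range, seed=int(child[1]) % (2**31)
    )
    effects = simulate_effects(cfg, rng)

    X = genotypes.dosages
    gwas_rows = slice(0, cfg.n_gwas)
    eval_rows = slice(cfg.n_gwas, n_total)

    gwas_geno = GenotypeMatrix(
        sample_ids=genotypes.sample_ids[gwas_rows],
        variants=genotypes.variants,
        dosages=X[gwas_rows],
    )
    traits = component_phenotypes(gwas_geno, effects, cfg, rng)
    est_weights = np.column_stack([
        run_gwas(gwas_geno, traits[:, i])["beta"].to_numpy()
        for i in range(cfg.n_scores)
    ])
    est_weights = np.nan_to_num(est_weights)

    eval_geno = GenotypeMatrix(
        sample_ids=genotypes.sample_ids[eval_rows],
        variants=genotypes.variants,
        dosages=X[eval_rows],
    )
    scores = _centered(eval_geno) @ est_weights  # estimated PRS per component
    draw = simulate_phenotype(eval_geno, effects, cfg, rng)
    y = draw.y

    n_eval = scores.shape[0]
    test_rows = np.arange(n_eval - cfg.n_test, n_eval)
    train_pool = np.arange(0, n_eval - cfg.n_test)

    specific = list(range(cfg.n_scores_specific))
    all_scores = list(range(cfg.n_scores))
    rows: list[dict] = []
    for n_train in cfg.n_train_grid:
        tr = train_pool[:n_train]
        for method, cols in (("prsmix", specific), ("prsmix_plus", all_scores)):
            ids = [f"PRS{i + 1}" for i in cols]
            panel = ScorePanel(
                sample_ids=[eval_geno.sample_ids[i] for i in tr],
                score_ids=ids,
                values=scores[np.ix_(tr, cols)],
            )
            weights = fit_mixture(
                panel, y[tr], family="continuous",
                seed=int(child[2]) % (2**31),
            )
            train_r2 = [
                partial_r2(y[tr], scores[tr, c]).r2 for c in cols
            ]
            best = cols[int(np.argmax(train_r2))]
            r2_best = partial_r2(y[test_rows], scores[test_rows, best]).r2
            if weights.informative:
                combined = scores[np.ix_(test_rows, cols)] @ weights.alpha_adj
                r2_comb = partial_r2(y[test_rows], combined).r2
            else:
                r2_comb = 0.0
            rows.append({
                "h2": h2, "n_train": n_train, "method": method,
                "replicate": replicate, "fold_ratio": r2_comb / r2_best,
                "r2_combined": r2_comb, "r2_best": r2_best,
            })
    return rows


def sweep_training_sizes(
    config: SimConfig, h2_grid: Sequence[float] | None = None
) -> SweepResult:
    """Run the training-size sweep over one or more heritability levels.

    Per replicate: simulate genotypes and correlated effects, estimate
    component-score weights by GWAS on a disjoint sample, fit PRSmix
    (trait-specific scores) and PRSmix+ (all scores) at every training size,
    and record the fold-ratio of combined vs best-single test-set R² on a
    fixed held-out test split. GWAS, training, and test samples are pairwise
    disjoint by construction.
    """
    if not config.n_train_grid:
        raise ValueError("n_train_grid must be non-empty")
    grid = tuple(h2_grid) if h2_grid is not None else (config.h2,)
    rows: list[dict] = []
    for h2 in grid:
        for rep in range(config.n_replicates):
            rows.extend(_replicate_fold_ratios(config, h2, rep))
    return SweepResult(data=pd.DataFrame(rows), config=config, h2_grid=grid)


def improvement_slope(
    sweep: SweepResult, method: str = "prsmix"
) -> dict[float, float]:
    """Slope of mean fold-ratio on log10(n_train), one value per h2 level."""
    out: dict[float, float] = {}
    data = sweep.data[sweep.data["method"] == method]
    for h2, grp in data.groupby("h2"):
        means = grp.groupby("n_train")["fold_ratio"].mean()
        if len(means) < 2:
            raise ValueError("need >= 2 distinct n_train values per h2")
        slope = np.polyfit(np.log10(means.index.to_numpy(dtype=float)),
                           means.to_numpy(), deg=1)[0]
        out[float(h2)] = float(slope)
    return out


def make_demo_study(
    n_samples: int = 2_000,
    m: int = 100,
    n_gwas: int = 4_000,
    h2: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[HarmonizedScoring], np.ndarray, np.ndarray]:
    """Small self-contained study: genotypes, harmonized scorings, outcome, covariates.

    The scorings carry GWAS-estimated weights for the six component traits;
    covariates are phenotype-independent age, sex, and 10 PCs. Doubles as the
    repository's fixture generator.
    """
    config = SimConfig(h2=h2, m_causal=m, n_gwas=n_gwas, n_test=1,
                       n_train_grid=(1,), n_replicates=1, seed=seed)
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(s) % (2**31) for s in ss.generate_state(3))
    rng = np.random.default_rng(s1)

    gwas_geno = simulate_genotypes(n_gwas, m, config.maf_range, seed=s2)
    effects = simulate_effects(config, rng)
    traits = component_phenotypes(gwas_geno, effects, config, rng)
    trait_labels = (["trait_specific"] * config.n_scores_specific
                    + [f"cross_trait_{i+1}" for i in range(config.n_scores_cross)])
    scorings = []
    for i in range(config.n_scores):
        est = run_gwas(gwas_geno, traits[:, i])["beta"].to_numpy()
        records = pd.DataFrame({
            "chrom": [k.chrom for k in gwas_geno.variants],
            "pos": [k.pos for k in gwas_geno.variants],
            "ref": [k.ref for k in gwas_geno.variants],
            "alt": [k.alt for k in gwas_geno.variants],
            "weight": np.nan_to_num(est),
        })
        scorings.append(HarmonizedScoring(
            score_id=f"PRS{i+1:03d}", records=records,
            trait_label=trait_labels[i],
        ))

    genotypes = simulate_genotypes(n_samples, m, config.maf_range, seed=s3)
    draw = simulate_phenotype(genotypes, effects, config, rng)
    covariates = np.column_stack([
        rng.normal(50, 10, n_samples),            # age
        rng.integers(0, 2, n_samples).astype(float),  # sex
        rng.normal(0, 1, (n_samples, 10)),        # 10 PCs
    ])
    return genotypes, scorings, draw.y, covariates
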