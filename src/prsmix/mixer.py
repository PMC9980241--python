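"""Training of PRSmix / PRSmix+ linear score combinations.

The combination model is a penalized (elastic-net) regression of the outcome
on candidate scores standardized to mean 0, variance 1 with training-split
statistics, with covariates entering unpenalized. The fitted mixing weights
``ω̂ᵢ`` on standardized scores are divided by the training-set standard
deviations ``σᵢ`` to give adjusted weights ``α̂ᵢ = ω̂ᵢ/σᵢ`` applicable to raw
scores, and per-variant combined effects ``γ̂ⱼ = Σᵢ α̂ᵢ βⱼᵢ`` (with βⱼᵢ = 0
where a variant is absent from score i) that can be written back out as an
ordinary scoring file.

PRSmix restricts the candidate set to scores sharing the outcome's trait
label; PRSmix+ admits every high-power score regardless of trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .pgs_io import HarmonizedScoring, VariantKey
from .prs_stats import (
    AccuracyEstimate,
    SelectionRule,
    liability_r2,
    partial_r2,
    select_high_power,
)
from .scoring import ScorePanel

__all__ = [
    "SplitSpec",
    "MixWeights",
    "AdjustedEffects",
    "ImprovementResult",
    "PrsmixResult",
    "NonInformativeModelError",
    "split_samples",
    "fit_mixture",
    "derive_snp_effects",
    "prsmix",
    "prsmix_plus",
    "improvement_test",
]


class NonInformativeModelError(RuntimeError):
    """Cross-validation selected the all-zero score model."""


@dataclass
class SplitSpec:
    """Train/test split specification (default 80/20, stratified for binary)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class MixWeights:
    """Fitted combination weights for a set of component scores."""

    score_ids: list[str]
    omega: np.ndarray          # coefficients on standardized scores
    sigma: np.ndarray          # training-set SDs of the raw scores
    mu: np.ndarray             # training-set means of the raw scores
    alpha_adj: np.ndarray      # omega / sigma, applicable to raw scores
    intercept: float
    covariate_coefs: np.ndarray
    family: str                # "continuous" | "binary"
    l1_ratio: float = 0.5
    cv_lambda: float = float("nan")

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.alpha_adj = np.asarray(self.alpha_adj, dtype=float)
        if not (len(self.omega) == len(self.sigma) == len(self.alpha_adj)
                == len(self.score_ids)):
            raise ValueError("weight vector lengths inconsistent with score ids")
        if np.any(self.sigma <= 0):
            raise ValueError("every training SD must be positive")

    @property
    def informative(self) -> bool:
        return bool(np.any(self.omega != 0))

    def combine(self, panel: ScorePanel) -> np.ndarray:
        """Raw-scale combined score Σᵢ α̂ᵢ·PRSᵢ for every panel sample."""
        values = panel.subset_scores(self.score_ids).values
        return values @ self.alpha_adj

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "score_id": self.score_ids,
            "omega": self.omega,
            "sigma": self.sigma,
            "alpha_adj": self.alpha_adj,
        })


@dataclass
class AdjustedEffects:
    """Per-variant combined effects γ̂ⱼ of the mixed score."""

    variants: list[VariantKey]
    gamma: np.ndarray
    score_id: str = "COMBINED"
    trait_label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if len(self.gamma) != len(self.variants):
            raise ValueError("one gamma per variant required")
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("non-finite combined effect")

    def to_harmonized(self) -> HarmonizedScoring:
        records = pd.DataFrame({
            "chrom": [k.chrom for k in self.variants],
            "pos": [k.pos for k in self.variants],
            "ref": [k.ref for k in self.variants],
            "alt": [k.alt for k in self.variants],
            "weight": self.gamma,
        })
        return HarmonizedScoring(self.score_id, records, trait_label=self.trait_label)


@dataclass
class ImprovementResult:
    """Mean fold-ratio of combined vs best-single R² with CI and t-test vs 1."""

    fold_ratios: np.ndarray
    mean_ratio: float
    ci95: tuple[float, float]
    p_value: float
    degenerate: bool = False


@dataclass
class PrsmixResult:
    """Output bundle of one PRSmix / PRSmix+ run."""

    weights: MixWeights
    effects: Optional[AdjustedEffects]
    test_accuracy: Optional[AccuracyEstimate]
    retained_ids: list[str]
    best_single_id: str
    best_single_test_accuracy: AccuracyEstimate
    train_ids: list[str]
    test_ids: list[str]


def split_samples(
    sample_ids: Sequence[str],
    phenotype: Sequence[float],
    spec: SplitSpec,
) -> tuple[list[str], list[str]]:
    """Deterministic train/test partition, stratified on case status when binary.

    Stratified splits preserve the case proportion within ±1 sample per
    stratum; both splits must contain every stratum.
    """
    sample_ids = list(sample_ids)
    y = np.asarray(phenotype, dtype=float)
    n = len(sample_ids)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(spec.seed)
    binary = set(np.unique(y)) <= {0.0, 1.0}

    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratify and binary:
        for level in np.unique(y):
            members = np.flatnonzero(y == level)
            perm = rng.permutation(members)
            n_train = int(round(spec.train_fraction * len(members)))
            if n_train == 0 or n_train == len(members):
                raise ValueError(
                    f"stratum {level} would be empty in train or test"
                )
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
    else:
        perm = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        train_idx = list(perm[:n_train])
        test_idx = list(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return [sample_ids[i] for i in train_idx], [sample_ids[i] for i in test_idx]


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = values.mean(axis=0)
    sigma = values.std(axis=0)
    return (values - mu) / np.where(sigma > 0, sigma, 1.0), mu, sigma


def fit_mixture(
    panel: ScorePanel,
    phenotype: Sequence[float],
    covariates=None,
    family: str = "continuous",
    l1_ratio: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
) -> MixWeights:
    """Fit the elastic-net score combination on the training split.

    Scores are standardized with training statistics; covariates (and the
    intercept) are unpenalized. The penalty strength is chosen by k-fold
    cross-validation at minimum CV loss. For the continuous family the
    unpenalized covariate block is concentrated out exactly (the joint
    solution equals the elastic net on covariate-residualized outcome and
    scores, with covariate coefficients recovered by least squares
    afterwards); the binary family uses a penalized logistic fit with a
    per-coefficient penalty vector that leaves covariates free.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(panel.sample_ids):
        raise ValueError("phenotype length does not match panel samples")
    values = panel.values
    sigma_raw = values.std(axis=0)
    zero_sd = [panel.score_ids[j] for j in np.flatnonzero(sigma_raw == 0)]
    if zero_sd:
        raise ValueError(f"score(s) with zero training SD: {zero_sd}")
    Z, mu, sigma = _standardize(values)

    n = len(y)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.size == 0:
            cov = None
    Xc = np.column_stack([np.ones(n)] + ([cov] if cov is not None else []))

    if family == "continuous":
        omega, intercept_covs, cv_lambda = _fit_continuous(
            Z, Xc, y, l1_ratio, n_folds, seed
        )
    elif family == "binary":
        if not set(np.unique(y)) <= {0.0, 1.0} or len(np.unique(y)) < 2:
            raise ValueError("binary family requires a 0/1 phenotype with both classes")
        omega, intercept_covs, cv_lambda = _fit_binary(
            Z, Xc, y, l1_ratio, n_folds, seed
        )
    else:
        raise ValueError(f"unknown family {family!r}")

    return MixWeights(
        score_ids=list(panel.score_ids),
        omega=omega,
        sigma=sigma,
        mu=mu,
        alpha_adj=omega / sigma,
        intercept=float(intercept_covs[0]),
        covariate_coefs=np.asarray(intercept_covs[1:], dtype=float),
        family=family,
        l1_ratio=l1_ratio,
        cv_lambda=cv_lambda,
    )


def _fit_continuous(Z, Xc, y, l1_ratio, n_folds, seed):
    # Frisch–Waugh: residualize y and scores on the unpenalized block, then
    # run the elastic net on the residuals — exact for a squared-error loss.
    beta_c, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
    proj = np.linalg.lstsq(Xc, Z, rcond=None)[0]
    y_res = y - Xc @ beta_c
    Z_res = Z - Xc @ proj
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    model = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, fit_intercept=False,
                         alphas=100, max_iter=100_000, tol=1e-7)
    model.fit(Z_res, y_res)
    omega = np.asarray(model.coef_, dtype=float)
    # covariate block refit against the score-adjusted outcome
    beta_c, _, _, _ = np.linalg.lstsq(Xc, y - Z @ omega, rcond=None)
    return omega, beta_c, float(model.alpha_)


def _fit_binary(Z, Xc, y, l1_ratio, n_folds, seed):
    n, p = Z.shape
    k_cov = Xc.shape[1]
    X = np.column_stack([Xc, Z])
    pen_mask = np.concatenate([np.zeros(k_cov), np.ones(p)])

    # glmnet-style penalty path from the null-model score gradient
    null_fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
    resid = y - null_fit.fittedvalues
    grad = np.abs(Z.T @ resid) / n
    lam_max = float(grad.max()) / max(l1_ratio, 1e-3)
    if lam_max <= 0:
        lam_max = 1e-3
    path = np.geomspace(lam_max, lam_max * 1e-2, 15)

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y, n_folds, rng)
    cv_dev = np.zeros(len(path))
    warm_start = np.zeros(X.shape[1])
    warm_start[0] = float(null_fit.params[0])
    for k in range(n_folds):
        tr = fold_of != k
        te = ~tr
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"cross-validation fold {k} contains a single class")
        params = warm_start
        for i, lam in enumerate(path):
            params = _glm_enet(y[tr], X[tr], lam * pen_mask, l1_ratio, params)
            eta = X[te] @ params
            prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            prob = np.clip(prob, 1e-10, 1 - 1e-10)
            cv_dev[i] += -2.0 * np.sum(y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob))
    best = int(np.argmin(cv_dev))
    params = warm_start
    for lam in path[:best + 1]:
        params = _glm_enet(y, X, lam * pen_mask, l1_ratio, params)
    omega = params[k_cov:]
    omega[np.abs(omega) < 1e-10] = 0.0
    return omega, params[:k_cov], float(path[best])


def _glm_enet(y, X, alpha_vec, l1_ratio, start_params=None):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit_regularized(
            method="elastic_net", alpha=alpha_vec, L1_wt=l1_ratio,
            maxiter=80, cnvrg_tol=1e-6, start_params=start_params,
        )
    return np.asarray(res.params, dtype=float)


def _stratified_folds(y, n_folds, rng) -> np.ndarray:
    fold_of = np.empty(len(y), dtype=int)
    for level in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == level))
        fold_of[members] = np.arange(len(members)) % n_folds
    return fold_of


def derive_snp_effects(
    weights: MixWeights,
    scorings: Sequence[HarmonizedScoring],
    score_id: str = "COMBINED",
    trait_label: str = "",
) -> AdjustedEffects:
    """Combine per-variant effects: γ̂ⱼ = Σᵢ α̂ᵢ·βⱼᵢ over the variant union.

    A variant absent from a component score contributes βⱼᵢ = 0 for that
    score. The fit intercept affects only the combined score's location and
    is discarded.
    """
    by_id = {s.score_id: s for s in scorings}
    missing = [s for s in weights.score_ids if s not in by_id]
    if missing:
        raise ValueError(f"scorings missing for score ids: {missing}")

    gamma: dict[VariantKey, float] = {}
    for sid, alpha in zip(weights.score_ids, weights.alpha_adj):
        for key, beta in by_id[sid].weight_map().items():
            gamma[key] = gamma.get(key, 0.0) + alpha * beta
    variants = sorted(gamma)
    return AdjustedEffects(
        variants=variants,
        gamma=np.array([gamma[k] for k in variants]),
        score_id=score_id,
        trait_label=trait_label,
        provenance={
            "score_ids": list(weights.score_ids),
            "alpha_adj": weights.alpha_adj.tolist(),
            "l1_ratio": weights.l1_ratio,
            "cv_lambda": weights.cv_lambda,
        },
    )


def _infer_family(y: np.ndarray) -> str:
    return "binary" if set(np.unique(y)) <= {0.0, 1.0} else "continuous"


def _evaluate(y, score, covariates, family, prevalence=None) -> AccuracyEstimate:
    if family == "binary":
        return liability_r2(y, score, covariates, prevalence=prevalence)
    return partial_r2(y, score, covariates)


def _run_combination(
    panel: ScorePanel,
    candidate_ids: Sequence[str],
    phenotype: Sequence[float],
    covariates,
    spec: SplitSpec,
    rule: SelectionRule | None,
    scorings: Sequence[HarmonizedScoring] | None,
    l1_ratio: float,
    prevalence: float | None,
    label: str,
) -> PrsmixResult:
    y = np.asarray(phenotype, dtype=float)
    family = _infer_family(y)
    candidate_ids = sorted(candidate_ids, key=panel.score_ids.index)
    if not candidate_ids:
        raise ValueError("no candidate scores for the outcome trait")

    train_ids, test_ids = split_samples(panel.sample_ids, y, spec)
    pos = {s: i for i, s in enumerate(panel.sample_ids)}
    tr = [pos[s] for s in train_ids]
    te = [pos[s] for s in test_ids]
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]

    sub = panel.subset_scores(candidate_ids)
    train_panel = sub.subset_samples(tr)
    cov_tr = cov[tr] if cov is not None else None
    cov_te = cov[te] if cov is not None else None
    for j, sid in enumerate(train_panel.score_ids):
        train_panel.accuracy[sid] = _evaluate(
            y[tr], train_panel.values[:, j], cov_tr, family, prevalence
        )
    retained = select_high_power(train_panel, rule)
    if not retained:
        raise ValueError(f"no {label} score survives the power/p-value filter")

    best_single_id = max(retained, key=lambda s: train_panel.accuracy[s].r2)
    best_single_test = _evaluate(
        y[te], sub.subset_samples(te).column(best_single_id), cov_te, family, prevalence
    )

    fit_panel = train_panel.subset_scores(retained)
    weights = fit_mixture(
        fit_panel, y[tr], cov_tr, family=family, l1_ratio=l1_ratio, seed=spec.seed
    )

    effects = None
    if scorings is not None:
        effects = derive_snp_effects(
            weights,
            [s for s in scorings if s.score_id in set(retained)],
            score_id=f"{label}_COMBINED",
        )

    test_accuracy = None
    if weights.informative:
        combined_te = sub.subset_scores(retained).subset_samples(te).values @ weights.alpha_adj
        test_accuracy = _evaluate(y[te], combined_te, cov_te, family, prevalence)

    return PrsmixResult(
        weights=weights,
        effects=effects,
        test_accuracy=test_accuracy,
        retained_ids=list(retained),
        best_single_id=best_single_id,
        best_single_test_accuracy=best_single_test,
        train_ids=train_ids,
        test_ids=test_ids,
    )


def prsmix(
    panel: ScorePanel,
    trait_label: str,
    phenotype: Sequence[float],
    covariates=None,
    spec: SplitSpec | None = None,
    rule: SelectionRule | None = None,
    scorings: Sequence[HarmonizedScoring] | None = None,
    l1_ratio: float = 0.5,
    prevalence: float | None = None,
) -> PrsmixResult:
    """Trait-specific combination: mix scores sharing the outcome's trait label.

    Scores are filtered on the training split by the power/p-value rule
    (``rule=None`` retains all trait-matched scores), combined by elastic
    net, and the combined score is evaluated on the held-out split alongside
    the best single score chosen on the training split. Trait-label matching
    is exact after case normalization.
    """
    spec = spec or SplitSpec()
    wanted = trait_label.strip().lower()
    candidates = [
        s for s in panel.score_ids
        if panel.trait_labels.get(s, "").strip().lower() == wanted
    ]
    if not candidates:
        raise ValueError(f"no score annotated with trait label {trait_label!r}")
    return _run_combination(
        panel, candidates, phenotype, covariates, spec, rule, scorings,
        l1_ratio, prevalence, label="PRSMIX",
    )


def prsmix_plus(
    panel: ScorePanel,
    phenotype: Sequence[float],
    covariates=None,
    spec: SplitSpec | None = None,
    rule: SelectionRule | None = None,
    scorings: Sequence[HarmonizedScoring] | None = None,
    l1_ratio: float = 0.5,
    prevalence: float | None = None,
) -> PrsmixResult:
    """Cross-trait combination: mix every high-power score regardless of trait."""
    spec = spec or SplitSpec()
    return _run_combination(
        panel, list(panel.score_ids), phenotype, covariates, spec, rule,
        scorings, l1_ratio, prevalence, label="PRSMIXPLUS",
    )


def improvement_test(
    r2_combined: Sequence[float], r2_best_single: Sequence[float]
) -> ImprovementResult:
    """Fold-ratio improvement summary across traits.

    Elementwise ratios combined/best-single, their mean with a normal-theory
    95% CI, and a two-tailed one-sample t-test of the ratios against 1.
    """
    a = np.asarray(r2_combined, dtype=float)
    b = np.asarray(r2_best_single, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("all R2 values must be positive")
    ratios = a / b
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1))
    n = len(ratios)
    if sd == 0:
        return ImprovementResult(
            fold_ratios=ratios, mean_ratio=mean, ci95=(mean, mean),
            p_value=1.0 if mean == 1.0 else 0.0, degenerate=True,
        )
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    t_res = stats.ttest_1samp(ratios, popmean=1.0)
    return ImprovementResult(
        fold_ratios=ratios,
        mean_ratio=mean,
        ci95=(mean - tcrit * se, mean + tcrit * se),
        p_value=float(t_res.pvalue),
    )
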