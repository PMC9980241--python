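"""Clinical-utility metrics for a polygenic score.

Category-free net reclassification improvement (NRI), incremental AUC of
nested risk models, odds ratios per SD and for the top score decile, and a
phenome-style per-phenotype logistic association scan with Bonferroni
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RiskModelPair",
    "NriResult",
    "DeltaAucResult",
    "OddsRatioResult",
    "AssocScanResult",
    "SeparationError",
    "category_free_nri",
    "incremental_auc",
    "or_per_sd",
    "top_decile_or",
    "assoc_scan",
    "auc",
]

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """The logistic model separates the outcome (unbounded estimate)."""


@dataclass
class RiskModelPair:
    """Predicted probabilities of a baseline and an augmented risk model."""

    baseline: np.ndarray
    augmented: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.augmented = np.asarray(self.augmented, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if not (len(self.baseline) == len(self.augmented) == len(self.outcome)):
            raise ValueError("model pair vectors must have equal length")
        for probs in (self.baseline, self.augmented):
            if np.min(probs) < 0 or np.max(probs) > 1:
                raise ValueError("predicted probabilities must lie in [0, 1]")
        if not set(np.unique(self.outcome)) <= {0.0, 1.0}:
            raise ValueError("outcome must be coded 0/1")

    def require_both_classes(self) -> None:
        if len(np.unique(self.outcome)) < 2:
            raise ValueError("outcome contains a single class")


@dataclass
class NriResult:
    nri_total: float
    nri_cases: float
    nri_controls: float
    ci95: tuple[float, float]
    n_bootstrap: int
    n_ties: int = 0


@dataclass
class DeltaAucResult:
    delta_auc: float
    auc_baseline: float
    auc_augmented: float
    ci95: tuple[float, float]
    n_bootstrap: int


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    log_or_se: float


@dataclass
class AssocScanResult:
    """Per-phenotype association results with a Bonferroni significance flag."""

    table: pd.DataFrame
    alpha: float
    bonferroni_threshold: float
    skipped: list[str] = field(default_factory=list)


def _nri_components(pair: RiskModelPair) -> tuple[float, float, int]:
    up = pair.augmented > pair.baseline
    down = pair.augmented < pair.baseline
    ties = int(np.sum(~up & ~down))
    case = pair.outcome == 1
    ctrl = ~case
    nri_cases = float(up[case].mean() - down[case].mean())
    nri_controls = float(down[ctrl].mean() - up[ctrl].mean())
    return nri_cases, nri_controls, ties


def category_free_nri(
    pair: RiskModelPair, n_bootstrap: int = 500, seed: int = 0
) -> NriResult:
    """Category-free NRI of augmented vs baseline risk predictions.

    NRI = P(up|case) − P(down|case) + P(down|control) − P(up|control), with
    up/down defined by strict probability movement (ties count as neither).
    The CI is a percentile bootstrap over samples.
    """
    pair.require_both_classes()
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    nri_cases, nri_controls, ties = _nri_components(pair)
    total = nri_cases + nri_controls

    rng = np.random.default_rng(seed)
    n = len(pair.outcome)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        while len(np.unique(pair.outcome[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        c, k, _ = _nri_components(RiskModelPair(
            pair.baseline[idx], pair.augmented[idx], pair.outcome[idx]
        ))
        boots[b] = c + k
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return NriResult(
        nri_total=total, nri_cases=nri_cases, nri_controls=nri_controls,
        ci95=(float(lo), float(hi)), n_bootstrap=n_bootstrap, n_ties=ties,
    )


def auc(outcome: np.ndarray, score: np.ndarray) -> float:
    """Rank (concordance) AUC with ties counted one half."""
    outcome = np.asarray(outcome, dtype=float)
    score = np.asarray(score, dtype=float)
    n_case = int(outcome.sum())
    n_ctrl = len(outcome) - n_case
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(score)
    return float((ranks[outcome == 1].sum() - n_case * (n_case + 1) / 2)
                 / (n_case * n_ctrl))


def incremental_auc(
    pair: RiskModelPair, n_bootstrap: int = 500, seed: int = 0
) -> DeltaAucResult:
    """ΔAUC = AUC(augmented) − AUC(baseline) with a percentile-bootstrap CI."""
    pair.require_both_classes()
    auc_base = auc(pair.outcome, pair.baseline)
    auc_aug = auc(pair.outcome, pair.augmented)
    delta = auc_aug - auc_base

    rng = np.random.default_rng(seed)
    n = len(pair.outcome)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        while len(np.unique(pair.outcome[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        boots[b] = (auc(pair.outcome[idx], pair.augmented[idx])
                    - auc(pair.outcome[idx], pair.baseline[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DeltaAucResult(
        delta_auc=delta, auc_baseline=auc_base, auc_augmented=auc_aug,
        ci95=(float(lo), float(hi)), n_bootstrap=n_bootstrap,
    )


def _logistic_or(predictor, outcome, covariates) -> OddsRatioResult:
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome contains a single class")
    n = len(y)
    X = [np.ones(n), np.asarray(predictor, dtype=float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.size:
            X.append(cov)
    X = np.column_stack(X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        warnings.filterwarnings("error", message=".*[Ss]eparation.*")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(
                f"logistic fit failed (possible separation): {exc}"
            ) from exc
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 50 or abs(coef) > 50:
        raise SeparationError("unbounded logistic estimate (separation)")
    zcrit = stats.norm.ppf(0.975)
    return OddsRatioResult(
        odds_ratio=float(np.exp(coef)),
        ci95=(float(np.exp(coef - zcrit * se)), float(np.exp(coef + zcrit * se))),
        p_value=float(fit.pvalues[1]),
        log_or_se=se,
    )


def or_per_sd(
    score: Sequence[float], outcome: Sequence[float], covariates=None
) -> OddsRatioResult:
    """Covariate-adjusted odds ratio per 1-SD increase of the score.

    The score is standardized over the evaluation sample, so the OR is
    invariant to the score's raw scale.
    """
    s = np.asarray(score, dtype=float)
    if s.std() == 0:
        raise ValueError("score is constant")
    return _logistic_or((s - s.mean()) / s.std(), outcome, covariates)


def top_decile_or(
    score: Sequence[float], outcome: Sequence[float], covariates=None
) -> OddsRatioResult:
    """Odds ratio for the top score decile versus the remaining population.

    The 90th percentile is taken from the evaluation sample itself; ties at
    or below the threshold stay in the reference group.
    """
    s = np.asarray(score, dtype=float)
    if len(s) < 20:
        raise ValueError("need at least 20 samples for a decile comparison")
    threshold = np.quantile(s, 0.9)
    top = (s > threshold).astype(float)
    if top.sum() == 0:
        raise ValueError("top decile group is empty (ties at the threshold)")
    return _logistic_or(top, outcome, covariates)


def assoc_scan(
    score: Sequence[float],
    phenotypes: pd.DataFrame,
    covariates=None,
    alpha: float = 0.05,
) -> AssocScanResult:
    """Per-phenotype logistic scan of a score across a binary phenotype matrix.

    Each phenotype column gets one covariate-adjusted logistic fit of outcome
    on the standardized score; significance is judged at the Bonferroni level
    ``alpha / n_tested``. Columns with a single class are skipped with a
    warning.
    """
    if phenotypes.shape[1] < 1:
        raise ValueError("need at least one phenotype column")
    s = np.asarray(score, dtype=float)
    s = (s - s.mean()) / s.std()

    rows = []
    skipped: list[str] = []
    for name in phenotypes.columns:
        y = np.asarray(phenotypes[name], dtype=float)
        if len(np.unique(y)) < 2:
            logger.warning("phenotype %s has a single class; skipped", name)
            skipped.append(str(name))
            continue
        try:
            res = _logistic_or(s, y, covariates)
            rows.append({
                "phenotype": str(name),
                "beta": float(np.log(res.odds_ratio)),
                "se": res.log_or_se,
                "p_value": res.p_value,
            })
        except SeparationError:
            logger.warning("phenotype %s separates on the score; skipped", name)
            skipped.append(str(name))

    n_tested = len(rows)
    if n_tested == 0:
        raise ValueError("no testable phenotype column")
    threshold = alpha / n_tested
    table = pd.DataFrame(rows)
    table["significant"] = table["p_value"] < threshold
    return AssocScanResult(
        table=table, alpha=alpha, bonferroni_threshold=threshold, skipped=skipped,
    )
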