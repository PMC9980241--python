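"""Accuracy, power, and variance statistics for polygenic scores.

The quantities implemented here drive the analytic pre-filtering of candidate
scores before combination:

* **partial R²** — variance explained by a score over and above covariates,
  ``R²(full) − R²(null)`` from least-squares fits.
* **liability R²** — observed-scale partial R² of a binary trait mapped to the
  latent liability scale with the prevalence-based transformation
  ``K²(1−K)² / (z² P(1−P))`` (Lee-style), which reduces to ``K(1−K)/z²`` when
  the population prevalence K equals the sample prevalence P.
* **non-centrality parameter** — ``λ = N R² / (1 − R²)`` of the score-trait
  association test.
* **power** — two-sided normal-approximation power
  ``1 − Φ(z_{1−α/2} − √λ) + Φ(z_{α/2} − √λ)``, equivalently the upper-tail
  mass of a non-central χ²₁(λ) beyond the central critical value.
* **se(R²)** — asymptotic standard error
  ``sqrt(4 R² (1−R²)² (N−2)² / ((N²−1)(N+3)))``.

Scores are retained for combination when power exceeds a threshold (default
0.95) and the association p-value passes a significance level (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AccuracyEstimate",
    "SelectionRule",
    "CollinearityError",
    "partial_r2",
    "liability_r2",
    "liability_factor",
    "ncp",
    "power",
    "power_ncchi2",
    "r2_se",
    "select_high_power",
    "evaluation_report",
]

_R2_CAP = 1.0 - 1e-12


class CollinearityError(ValueError):
    """The score is (numerically) collinear with the covariates."""


@dataclass
class AccuracyEstimate:
    """Prediction-accuracy summary for one score on one evaluation sample."""

    r2: float
    scale: str  # "observed-partial" | "liability"
    se_r2: float
    ncp: float
    power: float
    p_value: float
    n: int
    prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scale not in ("observed-partial", "liability"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if (self.scale == "liability") != (self.prevalence is not None):
            raise ValueError("prevalence must be present iff scale is liability")


@dataclass
class SelectionRule:
    """Retention thresholds for high-power scores."""

    power_threshold: float = 0.95
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.power_threshold < 1 and 0 < self.p_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")


def _design(n: int, covariates) -> np.ndarray:
    """Covariate design with intercept; covariates may be None/empty."""
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), cov])


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid, float(resid @ resid)


def ncp(n: int, r2: float) -> float:
    """Non-centrality parameter λ = n·r²/(1−r²) of the association test."""
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * r2 / (1.0 - r2)


def power(n: int, r2: float, alpha: float = 0.05) -> float:
    """Two-sided power of the score-trait association test.

    Normal approximation with the root non-centrality:
    ``1 − Φ(z_{1−α/2} − √λ) + Φ(z_{α/2} − √λ)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lam = ncp(n, r2)
    root = np.sqrt(lam)
    z_hi = stats.norm.ppf(1 - alpha / 2)
    z_lo = stats.norm.ppf(alpha / 2)
    return float(stats.norm.sf(z_hi - root) + stats.norm.cdf(z_lo - root))


def power_ncchi2(n: int, r2: float, alpha: float = 0.05) -> float:
    """Power via the non-central χ²₁(λ) beyond the central critical value.

    Agrees with :func:`power` to about 1e−3 over practical grids; the normal
    form is canonical here.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lam = ncp(n, r2)
    crit = stats.chi2.ppf(1 - alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam)) if lam > 0 else alpha


def r2_se(r2: float, n: int) -> float:
    """Asymptotic standard error of an estimated R².

    ``var(R²) = 4 R² (1−R²)² (n−2)² / ((n²−1)(n+3))``.
    """
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 3:
        raise ValueError("n must exceed 3")
    var = 4.0 * r2 * (1.0 - r2) ** 2 * (n - 2) ** 2 / ((n**2 - 1.0) * (n + 3.0))
    return float(np.sqrt(var))


def liability_factor(
    sample_prevalence: float, population_prevalence: float | None = None
) -> float:
    """Observed-to-liability R² conversion factor.

    With case proportion P in the sample and population prevalence K
    (default K = P), the factor is ``K²(1−K)² / (z² P(1−P))`` where z is the
    standard normal density at the K-quantile. At K = P = 0.5 this equals
    π/2.
    """
    P = sample_prevalence
    K = population_prevalence if population_prevalence is not None else P
    if not (0 < P < 1 and 0 < K < 1):
        raise ValueError("prevalences must lie in (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(K))
    return float(K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P)))


def partial_r2(
    phenotype: Sequence[float],
    score: Sequence[float],
    covariates=None,
    alpha: float = 0.05,
) -> AccuracyEstimate:
    """Partial R² of a score for a continuous trait, over and above covariates.

    Computed as the R² difference between the full least-squares model
    (score + covariates) and the null model (covariates only); the p-value is
    the nested-model F comparison on 1 df.
    """
    y = np.asarray(phenotype, dtype=float)
    s = np.asarray(score, dtype=float)
    n = len(y)
    Xnull = _design(n, covariates)
    if n <= Xnull.shape[1] + 2:
        raise ValueError("too few samples for the covariate model")
    if np.std(s) == 0:
        raise ValueError("score is constant")

    # collinearity guard: the score must retain variance beyond the covariates
    s_resid, s_rss = _ols_rss(s, Xnull)
    if s_rss <= 1e-10 * max(float(s @ s), 1e-300):
        raise CollinearityError("score is numerically collinear with the covariates")

    _, rss_null = _ols_rss(y, Xnull)
    Xfull = np.column_stack([Xnull, s])
    _, rss_full = _ols_rss(y, Xfull)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("phenotype is constant")
    r2 = max(0.0, (rss_null - rss_full) / tss)

    df_resid = n - Xfull.shape[1]
    if rss_full <= 1e-12 * tss:
        r2 = min(r2, 1.0)
        p_value = 0.0
    else:
        f_stat = (rss_null - rss_full) / (rss_full / df_resid)
        p_value = float(stats.f.sf(max(f_stat, 0.0), 1, df_resid))

    r2c = min(r2, _R2_CAP)
    return AccuracyEstimate(
        r2=r2,
        scale="observed-partial",
        se_r2=r2_se(r2c, n),
        ncp=ncp(n, r2c),
        power=power(n, r2c, alpha),
        p_value=p_value,
        n=n,
    )


def liability_r2(
    phenotype: Sequence[float],
    score: Sequence[float],
    covariates=None,
    prevalence: float | None = None,
    alpha: float = 0.05,
) -> AccuracyEstimate:
    """Liability-scale R² of a score for a binary trait.

    The observed-scale partial R² comes from least squares on the 0/1 outcome
    (linear probability model), then is multiplied by the liability
    transformation factor with K defaulting to the sample prevalence. The
    p-value is the Wald test on the score coefficient in a covariate-adjusted
    logistic model.
    """
    y = np.asarray(phenotype, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise ValueError("binary phenotype must contain both classes coded 0/1")
    n = len(y)
    sample_prev = float(y.mean())

    obs = partial_r2(y, score, covariates, alpha=alpha)
    factor = liability_factor(sample_prev, prevalence)
    r2_liab = obs.r2 * factor

    s = np.asarray(score, dtype=float)
    Xfull = np.column_stack([_design(n, covariates), s])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xfull).fit(disp=0, maxiter=200)
            p_value = float(fit.pvalues[-1])
        except Exception:
            p_value = obs.p_value  # fall back to the F comparison

    r2c = min(r2_liab, _R2_CAP)
    return AccuracyEstimate(
        r2=r2_liab,
        scale="liability",
        se_r2=r2_se(r2c, n),
        ncp=ncp(n, r2c),
        power=power(n, r2c, alpha),
        p_value=p_value,
        n=n,
        prevalence=prevalence if prevalence is not None else sample_prev,
    )


def select_high_power(panel, rule: SelectionRule | None = None) -> list[str]:
    """Return score ids passing the power/p-value retention rule, in panel order.

    ``panel`` is a :class:`~prsmix.scoring.ScorePanel` whose ``accuracy``
    mapping holds an :class:`AccuracyEstimate` per score (training split).
    ``rule=None`` retains every evaluated score.
    """
    retained: list[str] = []
    for score_id in panel.score_ids:
        est = panel.accuracy.get(score_id)
        if est is None:
            raise ValueError(f"score {score_id!r} has no accuracy estimate")
        if rule is None or (
            est.power > rule.power_threshold and est.p_value <= rule.p_threshold
        ):
            retained.append(score_id)
    return retained


def evaluation_report(panel, retained: Sequence[str]) -> pd.DataFrame:
    """Tabular evaluation report (score_id, scale, r2, se_r2, power, p, n, retained)."""
    rows = []
    retained_set = set(retained)
    for score_id in panel.score_ids:
        est = panel.accuracy.get(score_id)
        rows.append({
            "score_id": score_id,
            "trait_label": panel.trait_labels.get(score_id, ""),
            "scale": est.scale if est else "",
            "r2": est.r2 if est else np.nan,
            "se_r2": est.se_r2 if est else np.nan,
            "power": est.power if est else np.nan,
            "p_value": est.p_value if est else np.nan,
            "n": est.n if est else 0,
            "retained": score_id in retained_set,
        })
    return pd.DataFrame(rows)
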