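"""Cohort statistics: correlations, rater agreement, sensitivity regression.

Three analyses characterise the focal index at cohort level:

* Pearson correlation with a Fisher-z 95% CI and a t-test p-value, between
  the index and regional aeration / gas volume / lung weight / fluid balance
  (a Spearman option is provided for rank correlation);
* Cohen's kappa with an asymptotic CI for the agreement of two expert
  raters on the focal/diffuse dichotomy;
* an ordinary-least-squares sensitivity analysis of the index on the
  ventilatory settings (PEEP in cmH2O, respiratory rate in breaths/min,
  tidal volume per predicted body weight in ml/kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import CollinearityError, UndefinedCorrelationError, UndefinedKappaError

#: Column schema of a cohort table (one row per scan).
COHORT_COLUMNS = (
    "focal_index",
    "dorsal_diaphragmatic_nonaer_percent",
    "ventral_apical_hyper_percent",
    "total_gas_ml",
    "lung_weight_g",
    "fluid_balance_ml",
    "peep_cmH2O",
    "rr_per_min",
    "vt_per_pbw_ml_kg",
)

SENSITIVITY_PREDICTORS = ("peep_cmH2O", "rr_per_min", "vt_per_pbw_ml_kg")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str = "pearson"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class RaterTable:
    """2x2 agreement counts for two raters on the diffuse/focal dichotomy."""

    both_diffuse: int
    r1_diffuse_r2_focal: int
    r1_focal_r2_diffuse: int
    both_focal: int

    def __post_init__(self) -> None:
        counts = self.as_array()
        if np.any(counts < 0) or counts.sum() < 1:
            raise UndefinedKappaError("rater table needs nonnegative counts summing to >= 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.both_diffuse, self.r1_diffuse_r2_focal],
                [self.r1_focal_r2_diffuse, self.both_focal],
            ]
        )


@dataclass(frozen=True)
class RegressionResult:
    params: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    adj_r_squared: float
    f_pvalue: float
    n: int


def pearson_with_ci(
    x, y, alpha: float = 0.05, method: str = "pearson"
) -> CorrelationResult:
    """Sample correlation with a Fisher-z CI and a two-sided t-test p-value.

    ``method`` is "pearson" (default) or "spearman"; the Spearman variant
    applies the same Fisher machinery to the rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite; encode missing values explicitly upstream")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined: an input has zero variance")

    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, p=float(p), n=n, method=method)


def cohen_kappa(table: RaterTable, alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa of a 2x2 rater table with an asymptotic 95% CI.

    kappa = (p_o - p_e) / (1 - p_e) with the usual marginal expected
    agreement; the CI uses the large-sample standard error
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)) and is truncated to [-1, 1].
    """
    counts = table.as_array().astype(float)
    n = counts.sum()
    p = counts / n
    p_o = float(np.trace(p))
    marg1, marg2 = p.sum(axis=1), p.sum(axis=0)
    p_e = float(marg1 @ marg2)
    if abs(1.0 - p_e) < 1e-12:
        raise UndefinedKappaError("expected agreement is 1 (degenerate marginals)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = np.sqrt(p_o * (1.0 - p_o) / n) / (1.0 - p_e)
    half = sps.norm.ppf(1 - alpha / 2) * se
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(max(-1.0, kappa - half)),
        ci_high=float(min(1.0, kappa + half)),
        n=int(n),
    )


def sensitivity_regression(
    table: pd.DataFrame,
    outcome: str = "focal_index",
    predictors: tuple[str, ...] = SENSITIVITY_PREDICTORS,
) -> RegressionResult:
    """OLS of the focal index on the ventilatory settings, with intercept."""
    missing = [c for c in (outcome, *predictors) if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    y = table[outcome].to_numpy(dtype=float)
    X = table[list(predictors)].to_numpy(dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} scans for {k} predictors, got {n}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the columns involved in the deficiency via near-perfect pairwise fit
        offenders = [
            predictors[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise CollinearityError(f"rank-deficient design; offending columns: {offenders}")
    fit = sm.OLS(y, design).fit()
    names = ("intercept", *predictors)
    return RegressionResult(
        params=dict(zip(names, map(float, fit.params))),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue),
        n=n,
    )
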