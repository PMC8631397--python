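"""Classical tests and regression influence diagnostics.

This is the statistical layer the analysis pipeline runs on: two-sample
Student's t (pooled by default, Welch by flag), the two-sided F-test of
variance equality, the Kruskal-Wallis H-test, Pearson correlation with its
t-based two-sided p-value, and the simple-regression influence measures
(leverage, standardized residual, Cook's D, DFITS) used to exclude
influential subjects before correlating performance accuracy with latency.

Standard tests delegate to scipy / statsmodels; this module fixes the
conventions (two-sidedness, degrees of freedom, flagging cutoffs) and the
error contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .exceptions import ComputationError

__all__ = [
    "TestResult",
    "InfluenceCutoffs",
    "InfluenceReport",
    "students_t",
    "variance_f_test",
    "kruskal_wallis",
    "pearson",
    "regression_influence",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is a scalar for t / H / r and a ``(df1, df2)`` pair for the
    F-test; ``n`` mirrors the sample size(s) the statistic was computed on.
    """

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    n: int | tuple[int, ...]


def _as_sample(x: Sequence[float], name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def students_t(
    sample_a: Sequence[float], sample_b: Sequence[float], pooled: bool = True
) -> TestResult:
    """Two-sample t-test for a difference in means.

    ``pooled=True`` gives the classical Student form (equal-variance,
    df = n_a + n_b - 2); ``pooled=False`` gives Welch's unequal-variance
    variant with Satterthwaite df.  p is two-sided.
    """
    a = _as_sample(sample_a, "sample_a")
    b = _as_sample(sample_b, "sample_b")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ComputationError("both samples are constant; t is undefined")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    df = a.size + b.size - 2 if pooled else float(res.df)
    return TestResult(float(res.statistic), df, float(res.pvalue), (a.size, b.size))


def variance_f_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TestResult:
    """F-test of equal variances, F = s²_a / s²_b, two-sided p."""
    a = _as_sample(sample_a, "sample_a")
    b = _as_sample(sample_b, "sample_b")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        raise ComputationError("zero variance; F is undefined")
    f = va / vb
    df = (a.size - 1, b.size - 1)
    cdf = sps.f.cdf(f, *df)
    p = 2 * min(cdf, 1 - cdf)
    return TestResult(float(f), df, float(min(p, 1.0)), (a.size, b.size))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H-test across ``groups`` (tie-corrected, chi² p)."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrs = [_as_sample(g, f"group {i}", min_n=1) for i, g in enumerate(groups)]
    if sum(a.size for a in arrs) < 3:
        raise ValueError("kruskal_wallis needs a total of at least 3 observations")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise ComputationError("H is undefined when all observations are tied")
    try:
        res = sps.kruskal(*arrs)
    except ValueError as exc:
        raise ComputationError(f"H is undefined: {exc}") from exc
    return TestResult(
        float(res.statistic),
        len(arrs) - 1,
        float(res.pvalue),
        tuple(a.size for a in arrs),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided p from t = r·sqrt((n-2)/(1-r²))."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    xa = _as_sample(xa, "x", min_n=3)
    ya = _as_sample(ya, "y", min_n=3)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ComputationError("constant input; r is undefined")
    res = sps.pearsonr(xa, ya)
    return TestResult(float(res.statistic), xa.size - 2, float(res.pvalue), xa.size)


@dataclass(frozen=True)
class InfluenceCutoffs:
    """Flagging rules for simple-regression influence diagnostics.

    With p = 2 parameters (intercept + slope) and n observations, an
    observation is flagged when any of the following holds:

    * leverage h_i > ``leverage_factor`` · p / n,
    * |standardized residual| > ``residual``,
    * Cook's D_i > the ``cooks_f_quantile`` quantile of F(p, n - p),
    * |DFITS_i| > ``dfits_factor`` · sqrt(p / n).
    """

    leverage_factor: float = 3.0
    residual: float = 2.0
    cooks_f_quantile: float = 0.5
    dfits_factor: float = 2.0


@dataclass
class InfluenceReport:
    """Per-observation influence diagnostics for y ~ x."""

    leverage: np.ndarray
    standardized_residual: np.ndarray
    cooks_d: np.ndarray
    dfits: np.ndarray
    flagged: np.ndarray
    reasons: list[tuple[str, ...]] = field(default_factory=list)
    cutoffs: InfluenceCutoffs = field(default_factory=InfluenceCutoffs)

    @property
    def flagged_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flagged)


def regression_influence(
    x: Sequence[float],
    y: Sequence[float],
    cutoffs: InfluenceCutoffs | None = None,
) -> InfluenceReport:
    """Influence diagnostics for the simple linear regression y ~ x.

    Leverage is the hat-matrix diagonal h_i = 1/n + (x_i - x̄)²/Sxx;
    standardized residuals are internally studentized; Cook's D and DFITS
    follow their standard definitions (DFITS externally studentized).
    """
    xa = _as_sample(np.asarray(x, dtype=float), "x", min_n=4)
    ya = _as_sample(np.asarray(y, dtype=float), "y", min_n=4)
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if np.ptp(xa) == 0:
        raise ComputationError("constant x; regression is undefined")
    cut = cutoffs or InfluenceCutoffs()
    n, p = xa.size, 2

    fit = sm.OLS(ya, sm.add_constant(xa)).fit()
    infl = OLSInfluence(fit)
    leverage = np.asarray(infl.hat_matrix_diag)
    # exact fit: residual scale is 0, standardized measures are defined as 0
    if fit.ssr <= 1e-14 * max(1.0, float(np.dot(ya, ya))):
        std_resid = np.zeros(n)
        cooks = np.zeros(n)
        dfits = np.zeros(n)
    else:
        std_resid = np.asarray(infl.resid_studentized_internal)
        cooks = np.asarray(infl.cooks_distance[0])
        dfits = np.asarray(infl.dffits[0])

    lev_cut = cut.leverage_factor * p / n
    cooks_cut = sps.f.ppf(cut.cooks_f_quantile, p, n - p)
    dfits_cut = cut.dfits_factor * math.sqrt(p / n)

    reasons: list[tuple[str, ...]] = []
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        why = []
        if leverage[i] > lev_cut:
            why.append("leverage")
        if abs(std_resid[i]) > cut.residual:
            why.append("residual")
        if cooks[i] > cooks_cut:
            why.append("cooks_d")
        if abs(dfits[i]) > dfits_cut:
            why.append("dfits")
        reasons.append(tuple(why))
        flagged[i] = bool(why)

    return InfluenceReport(leverage, std_resid, cooks, dfits, flagged, reasons, cut)
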