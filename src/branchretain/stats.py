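"""Shared statistical kernel: dosage OLS, directional two-group tests, exact 2x2 tests.

The regressions are deliberately unadjusted simple OLS — genotype dosage (or a
binary genotype grouping) is the only predictor, matching how coverage and
enzyme-activity phenotypes are analyzed here. The "one-sided" group comparison
is a directional pooled-variance t test expressed as a two-group OLS, so its
two-sided p equals the classic t-test p exactly and the one-sided p is the
appropriate half (or complement) depending on the sign of the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class DosageRegressionResult:
    slope: float
    intercept: float
    se: float
    t: float
    p: float  # two-sided
    r2_unadjusted: float
    n: int
    grouping: str = "dosage"  # "dosage" or "binary"
    p_one_sided: Optional[float] = None


def ols_dosage(y: Sequence[float], g: Sequence[float], grouping: str = "dosage") -> DosageRegressionResult:
    """Simple OLS of ``y`` on dosage codes ``g`` with closed-form inference.

    p is two-sided from the t distribution with n-2 df. A response with zero
    residual contrast (constant y) is reported as slope 0, r^2 0, p 1 rather
    than an error: a flat phenotype carries no association evidence.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if len(g) != n:
        raise ValueError("y and g length mismatch")
    if np.var(g) == 0:
        raise ValueError("no contrast: predictor has zero variance")
    if np.var(y) == 0:
        return DosageRegressionResult(
            slope=0.0, intercept=float(y[0]), se=0.0, t=0.0, p=1.0,
            r2_unadjusted=0.0, n=n, grouping=grouping,
        )
    fit = sps.linregress(g, y)
    return DosageRegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        se=float(fit.stderr),
        t=float(fit.slope / fit.stderr) if fit.stderr > 0 else 0.0,
        p=float(fit.pvalue),
        r2_unadjusted=float(fit.rvalue**2),
        n=n,
        grouping=grouping,
    )


def one_sided_pair_test(
    group_a: Sequence[float], group_b: Sequence[float], direction: str = "less"
) -> DosageRegressionResult:
    """Directional two-group comparison as an indicator-predictor OLS.

    ``direction`` states the alternative for group_b relative to group_a:
    "less" expects a negative slope (b below a), "greater" a positive one.
    One-sided p is half the two-sided p when the estimate's sign matches the
    stated direction, 1 minus that half otherwise, and exactly 0.5 at zero.
    """
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    y = np.concatenate([a, b])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    if np.var(y) == 0:
        return DosageRegressionResult(
            slope=0.0, intercept=float(y[0]), se=0.0, t=0.0, p=1.0,
            r2_unadjusted=0.0, n=len(y), grouping="binary", p_one_sided=0.5,
        )
    res = ols_dosage(y, g, grouping="binary")
    sign = -1.0 if direction == "less" else 1.0
    if res.slope * sign > 0:
        p1 = res.p / 2
    elif res.slope * sign < 0:
        p1 = 1 - res.p / 2
    else:
        p1 = 0.5
    return DosageRegressionResult(
        slope=res.slope, intercept=res.intercept, se=res.se, t=res.t, p=res.p,
        r2_unadjusted=res.r2_unadjusted, n=res.n, grouping="binary", p_one_sided=p1,
    )


def fisher_2x2(table: Sequence[Sequence[int]]) -> tuple[float, Optional[float]]:
    """Exact two-sided Fisher test on a 2x2 count table.

    Returns (odds_ratio, p). p is None (undefined) when a margin is all zero,
    leaving the conditional distribution degenerate.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        odds = np.nan
        if t[0, 1] * t[1, 0] > 0:
            odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        return float(odds), None
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if n == 0:
        raise ValueError("n must be positive")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def bonferroni(pvals: Sequence[float]) -> list[float]:
    """Optional multiplicity correction; never applied by default."""
    m = len(pvals)
    return [min(1.0, p * m) for p in pvals]
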