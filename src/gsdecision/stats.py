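"""Comparison statistics for selection experiments.

Welch's two-sample t-test compares replicate-level means or variances
between two selection criteria; Hotelling's two-sample T^2 compares
multivariate means of selected groups; the selection-overlap report counts
how many lines two equal-size selections disagree on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ComparisonReport:
    """One comparison: statistic, degrees of freedom, p-value, optional overlap."""

    contrast: str
    statistic: float
    df: float | tuple
    pvalue: float
    overlap_fraction: float | None = None


def two_sample_t(x, y, *, contrast: str = "") -> ComparisonReport:
    """Welch (unequal-variance) two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return ComparisonReport(contrast, 0.0, float(x.size + y.size - 2), 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return ComparisonReport(contrast, float(res.statistic), float(res.df),
                            float(res.pvalue))


def hotelling_t2(X, Y, *, contrast: str = "") -> ComparisonReport:
    """Hotelling's two-sample T^2 test for equal multivariate means.

    ``T^2 = n1 n2 / (n1 + n2) d' Sp^-1 d`` with the pooled covariance
    ``Sp``; the p-value comes from the exact F transform
    ``F = (n1 + n2 - t - 1) T^2 / ((n1 + n2 - 2) t)`` with
    ``(t, n1 + n2 - t - 1)`` degrees of freedom.  At t = 1 the statistic
    reduces to the square of the pooled two-sample t.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("groups must share the trait dimension")
    n1, n2, t = X.shape[0], Y.shape[0], X.shape[1]
    if n1 + n2 - 2 <= t:
        raise ValueError("too few samples for the trait dimension")
    d = X.mean(axis=0) - Y.mean(axis=0)
    Sp = ((n1 - 1) * np.cov(X, rowvar=False, ddof=1).reshape(t, t)
          + (n2 - 1) * np.cov(Y, rowvar=False, ddof=1).reshape(t, t)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(Sp, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance") from exc
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    f_stat = (n1 + n2 - t - 1) / ((n1 + n2 - 2) * t) * t2
    df = (t, n1 + n2 - t - 1)
    pvalue = float(stats.f.sf(f_stat, *df))
    return ComparisonReport(contrast, t2, df, pvalue)


def selection_overlap(a, b) -> tuple[int, float]:
    """``(count differing, fraction differing)`` between equal-size id sets."""
    a, b = set(a), set(b)
    if len(a) != len(b):
        raise ValueError(f"selections differ in size: {len(a)} vs {len(b)}")
    diff = len(a - b)
    return diff, diff / len(a)
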