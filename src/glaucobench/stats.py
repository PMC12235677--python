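"""Nonparametric comparison tests used in within-report group analyses.

Thin contract wrappers around scipy.stats: Wilcoxon signed-rank for paired
location shifts, Kruskal-Wallis for multi-group location, and Pearson's
chi-square for categorical association.  Significance conventions (two-sided
p-values) match routine clinical reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

__all__ = [
    "TestResult", "paired_location_test", "groups_location_test",
    "categorical_association_test",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def paired_location_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic Wilcoxon treatment); if every
    difference is zero the result is degenerate with p = 1.  Small samples
    without ties use the exact null distribution; larger ones the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    n = int(nonzero.size)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=0,
                          method="wilcoxon-signed-rank")
    has_ties = np.unique(np.abs(nonzero)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=n, method="wilcoxon-signed-rank")


def groups_location_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more independent groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise InsufficientDataError("every group needs at least one value")
    n = int(sum(a.size for a in arrays))
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # All observations identical: no location information, H = 0.
        return TestResult(statistic=0.0, p_value=1.0, n=n, method="kruskal-wallis")
    res = sps.kruskal(*arrays)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=n, method="kruskal-wallis")


def categorical_association_test(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square test of independence on a 2-D contingency table."""
    observed = np.asarray(table)
    if observed.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (observed < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("every row and column marginal must be positive")
    res = sps.chi2_contingency(observed, correction=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=int(observed.sum()), method="chi-square")
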