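"""Thin statistical utilities shared by the comparative analyses.

All routines delegate to scipy; the only hand-written piece is the two-sided
variance-ratio F test (scipy exposes the F distribution but not the test
itself). Degenerate inputs (zero variance, empty groups) are surfaced as a
missing p-value rather than an exception, so cohort loops never abort on one
pathological organism.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

TestResult = tuple[float | None, float | None]  # (statistic, p_value)


def _clean(result) -> TestResult:
    stat, p = float(result[0]), float(result[1])
    if math.isnan(stat) or math.isnan(p):
        return None, None
    return stat, p


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample t-test with unequal variances, two-sided."""
    if len(x) < 2 or len(y) < 2:
        return None, None
    return _clean(sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired-sample t-test, two-sided; missing p on zero difference variance."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2 or np.std(x - y) == 0:
        return None, None
    return _clean(sps.ttest_rel(x, y))


def variance_f_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided F test of equality of variances (var(x)/var(y) ratio)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        return None, None
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        return None, None
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    cdf = sps.f.cdf(f, dfx, dfy)
    p = 2 * min(cdf, 1 - cdf)
    return float(f), float(min(p, 1.0))


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test on a 2x2 contingency table (odds ratio, p)."""
    res = sps.fisher_exact(np.asarray(table, dtype=int))
    return float(res[0]), float(res[1])


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    res = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return _clean((res.statistic, res.pvalue))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    res = sps.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return _clean((res.statistic, res.pvalue))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values, capped at 1."""
    n = len(p_values)
    return [min(1.0, p * n) for p in p_values]
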