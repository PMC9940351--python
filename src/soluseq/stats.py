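"""Shared statistical primitives.

Thin, validated wrappers around scipy/statsmodels: Welch's t, the one-sided
Wilcoxon rank-sum (exact for small tie-free samples), the Pearson
correlation t-test with a minimum-n guard, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    alternative: str
    n: tuple[int, ...]

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def _check(a, b, alternative, min_n=2):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"each group needs at least {min_n} observations")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN in input")
    return a, b


def welch_t(a, b, alternative: str = "two-sided") -> TestResult:
    """Welch's unequal-variance t-test (Welch-Satterthwaite df)."""
    a, b = _check(a, b, alternative)
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, (len(a), len(b)))


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both samples have n <= 20 and the
    pooled data are tie-free; otherwise the tie-corrected normal
    approximation.
    """
    a, b = _check(a, b, alternative, min_n=1)
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(a) <= 20 and len(b) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, (len(a), len(b)))


def pearson_test(x, y, alternative: str = "two-sided", min_n: int = 30) -> TestResult:
    """Pearson r with its t-distributed p-value (n - 2 df).

    Correlation tests on small groups are unstable, so groups smaller than
    ``min_n`` (default 30) are refused; pass ``min_n=0`` to override.
    """
    x, y = _check(x, y, alternative)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < min_n:
        raise ValueError(
            f"n={len(x)} below the minimum group size {min_n}; "
            "pass min_n=0 to override"
        )
    res = sps.pearsonr(x, y, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, (len(x),))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
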