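"""Shared statistical kernels with documented conventions.

Thin, convention-pinning wrappers around scipy so that every module in the
package reports identical statistics for identical questions: unpaired
two-tailed Wilcoxon rank-sum tests for comparing median distributions,
Pearson correlation with a t-based p-value, and Benjamini-Hochberg FDR
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p}")


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Unpaired two-tailed Wilcoxon (Mann-Whitney) rank-sum test.

    Mid-ranks are used for ties.  The null distribution is exact when
    n_x + n_y <= 20 and the data are tie-free; otherwise the normal
    approximation with tie correction and continuity correction is used.

    Returns the rank-sum statistic U for ``x`` and a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method=f"wilcoxon-{method}",
        n=int(x.size + y.size),
    )


def pearson(x, y) -> TestResult:
    """Pearson correlation r with the two-sided t-based p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(statistic=float("nan"), p=1.0, method="pearson", n=int(x.size))
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        method="pearson",
        n=int(x.size),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving.

    NaN entries are propagated as NaN and excluded from the adjustment of
    the remaining p-values.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[ok] = res
    return out
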