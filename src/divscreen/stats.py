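"""Rank-based statistical primitives.

Small-sample p-values are exact (tie-aware enumeration); larger samples use
the standard normal approximations with tie and continuity corrections, as
implemented in :mod:`scipy.stats`. Multiple-testing adjustment is
Benjamini-Hochberg step-up via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "bh_adjust",
]

# enumeration is cheap up to these sizes; beyond them the normal
# approximation is accurate enough for rank statistics
_RANKSUM_EXACT_MAX_N = 10
_SIGNRANK_EXACT_MAX_N = 15


@dataclass
class GroupTestResult:
    """Outcome of a two-group or paired rank test."""

    statistic: float
    p_value: float
    median_a: float | None = None
    median_b: float | None = None
    direction: str | None = None  # 'greater', 'less' or 'none'
    degenerate: bool = False
    method: str = ""


def _ranksum_exact_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact rank-sum p by enumerating all assignments of the pooled values.

    Average ranks are used throughout so ties are handled exactly.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, m = len(x), len(y)
    observed = float(ranks[:n].sum())
    total = 0
    ge = le = 0
    idx = range(n + m)
    for comb in combinations(idx, n):
        s = float(ranks[list(comb)].sum())
        total += 1
        if s >= observed - 1e-9:
            ge += 1
        if s <= observed + 1e-9:
            le += 1
    if alternative == "greater":
        p = ge / total
    elif alternative == "less":
        p = le / total
    else:
        p = min(1.0, 2.0 * min(ge, le) / total)
    return observed, p


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> GroupTestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test between two independent samples.

    Exact tie-aware enumeration when ``len(x)+len(y) <= 10``; otherwise the
    normal approximation with tie correction and continuity correction.

    Parameters
    ----------
    x, y
        Value vectors, each nonempty.
    alternative
        'two-sided' (default), 'greater' (x tends larger) or 'less'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return GroupTestResult(
            statistic=float(sps.rankdata(pooled)[: x.size].sum()),
            p_value=1.0,
            median_a=med_x,
            median_b=med_y,
            direction="none",
            degenerate=True,
            method="degenerate",
        )
    if x.size + y.size <= _RANKSUM_EXACT_MAX_N:
        stat, p = _ranksum_exact_p(x, y, alternative)
        method = "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        # report the rank-sum of x rather than the U statistic
        stat = float(res.statistic + x.size * (x.size + 1) / 2.0)
        p = float(res.pvalue)
        method = "normal-approx"
    if med_x > med_y:
        direction = "greater"
    elif med_x < med_y:
        direction = "less"
    else:
        direction = "none"
    return GroupTestResult(stat, p, med_x, med_y, direction, False, method)


def _signed_rank_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign patterns (tie-aware)."""
    ranks = sps.rankdata(np.abs(diffs))
    observed = float(ranks[diffs > 0].sum())
    n = len(diffs)
    mean = ranks.sum() / 2.0
    obs_dev = abs(observed - mean)
    count = 0
    total = 2**n
    for signs in product((0, 1), repeat=n):
        s = float(sum(r for r, b in zip(ranks, signs) if b))
        if abs(s - mean) >= obs_dev - 1e-9:
            count += 1
    return observed, min(1.0, count / total)


def wilcoxon_signed_rank(x, y) -> GroupTestResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped (Wilcoxon's original treatment). Exact
    enumeration of the 2^n sign patterns for n <= 15 nonzero differences,
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    diffs = diffs[diffs != 0]
    med_x, med_y = float(np.median(x)), float(np.median(y))
    if diffs.size == 0:
        return GroupTestResult(0.0, 1.0, med_x, med_y, "none", True, "degenerate")
    if diffs.size < 3:
        raise ValueError("need at least 3 nonzero paired differences")
    if diffs.size <= _SIGNRANK_EXACT_MAX_N:
        stat, p = _signed_rank_exact_p(diffs)
        method = "exact"
    else:
        res = sps.wilcoxon(diffs, zero_method="wilcox", correction=False, method="approx")
        stat, p, method = float(res.statistic), float(res.pvalue), "normal-approx"
    direction = "greater" if med_x > med_y else ("less" if med_x < med_y else "none")
    return GroupTestResult(stat, p, med_x, med_y, direction, False, method)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with its t-approximation p-value.

    Returns ``(nan, nan)`` when either vector is constant (no ranking
    information), matching the missing-with-reason contract upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
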