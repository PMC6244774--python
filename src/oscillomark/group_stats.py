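"""Rank-based group comparisons: exact Mann-Whitney U, tie-corrected Kruskal-Wallis, t-test.

These link the activity biomarker to the ordinal NLGN3 expression tiers.  The
cohort is small (group sizes 12/6/3), where the normal approximation to the U
null is unreliable; the exact null distribution is therefore computed by
enumeration whenever the pooled sample is small and untied, which is what
reproduces the published two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as _stats

__all__ = [
    "GroupTestResult",
    "midranks",
    "exact_u_distribution",
    "mann_whitney_u",
    "kruskal_wallis",
    "two_sample_t",
]

#: pooled-sample-size limit under which the exact U null is enumerated
EXACT_U_LIMIT = 25


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of a two- or k-sample location test."""

    statistic_name: str  # "U", "H" or "t"
    statistic: float
    p_value: float
    method: str  # "exact", "chi_square_approx", "normal_approx", "pooled", "welch"
    group_sizes: tuple[int, ...]
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing the average (mid) rank."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=None)
def exact_u_distribution(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of labelings per U value under the exact null, U = 0..n1*n2.

    ``counts[u]`` is the number of the C(n1+n2, n1) equally likely rank
    assignments of the pooled (untied) sample in which the first group attains
    Mann-Whitney statistic u.  Computed by the standard lattice recurrence
    f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u) in exact integers.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("group sizes must be nonnegative")
    # table[u] for current (i, j); iterate i = 0..n1, j = 0..n2
    prev = [[0] * (n1 * n2 + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1  # i = 0: only U = 0
    for i in range(1, n1 + 1):
        cur = [[0] * (n1 * n2 + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1
        for j in range(1, n2 + 1):
            row, up, left = cur[j], prev[j], cur[j - 1]
            for u in range(n1 * n2 + 1):
                row[u] = left[u] + (up[u - j] if u >= j else 0)
        prev = cur
    return tuple(prev[n2])


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    n1, n2 = len(x), len(y)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    return u1, n1 * n2 - u1, pooled


def mann_whitney_u(x, y) -> GroupTestResult:
    """Two-sided Mann-Whitney U test, reported as U = min(U1, U2).

    For pooled samples of at most 25 untied observations the p-value is exact:
    twice the lower-tail probability of the enumerated null, capped at 1.
    Otherwise the normal approximation with the tie-corrected variance is used.
    The min(U1, U2) convention matches mainstream clinical-statistics software.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u1, u2, pooled = _u_statistics(x, y)
    u = min(u1, u2)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= EXACT_U_LIMIT and not has_ties:
        counts = exact_u_distribution(n1, n2)
        total = sum(counts)
        lower = sum(counts[: int(u) + 1])
        p = min(1.0, 2.0 * lower / total)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            raise ValueError("zero variance: all pooled values identical")
        z = (u1 - mu) / np.sqrt(sigma2)
        p = float(2.0 * _stats.norm.sf(abs(z)))
        method = "normal_approx"
    return GroupTestResult("U", float(u), p, method, (n1, n2))


def kruskal_wallis(groups) -> GroupTestResult:
    """Kruskal-Wallis H with midranks and tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    if n < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: rank variance is zero")
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        rbar = ranks[start : start + size].mean()
        h += size * (rbar - (n + 1) / 2.0) ** 2
        start += size
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    h /= correction
    df = len(groups) - 1
    p = float(_stats.chi2.sf(h, df))
    return GroupTestResult("H", float(h), p, "chi_square_approx", tuple(sizes), df=float(df))


def two_sample_t(x, y, pooled: bool = True) -> GroupTestResult:
    """Two-sided two-sample t-test; pooled-variance by default, Welch optional."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("zero variance in both samples")
    diff = x.mean() - y.mean()
    if pooled:
        df = n1 + n2 - 2.0
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        method = "pooled"
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        method = "welch"
    t = diff / se
    p = float(2.0 * _stats.t.sf(abs(t), df))
    return GroupTestResult("t", float(t), p, method, (n1, n2), df=float(df))
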