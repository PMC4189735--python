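"""Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) test.

Small, tie-free comparisons use the exact null distribution of the
Mann-Whitney U statistic (dynamic-programming enumeration); everything else
uses the normal approximation with tie correction and a continuity
correction that shrinks |U - mean| toward zero, so identical groups give
p = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RankSumResult", "rank_sum_test", "exact_u_distribution"]

EXACT_MAX_GROUP = 8  # largest min(n, m) for which the exact path is used


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    method: str  # "exact" or "approx"
    n1: int
    n2: int


def exact_u_distribution(n: int, m: int) -> np.ndarray:
    """Counts of each U value (0..n*m) over all C(n+m, n) rank assignments.

    Recurrence: c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u).
    """
    table = np.zeros((n + 1, m + 1, n * m + 1), dtype=np.float64)
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            table[i, j, :] = table[i, j - 1, :]
            table[i, j, j : i * j + 1] += table[i - 1, j, : (i - 1) * j + 1]
    return table[n, m, :]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties, via midranks."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n].sum()
    return float(r1 - n * (n + 1) / 2)


def rank_sum_test(x, y, method: str = "auto") -> RankSumResult:
    """Two-sided rank-sum test of location shift between two samples.

    ``method`` is ``"exact"``, ``"approx"`` or ``"auto"`` (exact when
    min(n, m) <= 8 and the pooled sample has no ties).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (min(n, m) <= EXACT_MAX_GROUP and not has_ties) else "approx"
    if method == "exact" and has_ties:
        raise ValueError("exact rank-sum path requires tie-free data")

    u = _u_statistic(x, y)
    if method == "exact":
        dist = exact_u_distribution(n, m)
        total = dist.sum()
        k = int(round(u))
        p_le = dist[: k + 1].sum() / total
        p_ge = dist[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(u, float(p), "exact", n, m)

    mu = n * m / 2.0
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:  # every value identical: no evidence of shift
        return RankSumResult(u, 1.0, "approx", n, m)
    d = max(abs(u - mu) - 0.5, 0.0)  # continuity correction toward the mean
    z = d / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return RankSumResult(u, float(p), "approx", n, m)
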