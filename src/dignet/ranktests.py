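"""One-sided Wilcoxon rank-sum test (alternative: first sample greater).

Exact for small samples, normal approximation with tie correction otherwise.

Tie convention for the exact test: with no tied values the p-value is the
classical ``P(T* >= t)``; with ties, midranks are used and the mid-p
``P(T* > t) + 0.5 * P(T* = t)`` is reported, so two identical samples give
exactly 0.5.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import GroupingError

__all__ = ["rank_sum_greater", "EXACT_MAX"]

#: exact enumeration is used when both groups are at most this large
EXACT_MAX = 12


def _exact_ranksum_distribution(double_ranks: np.ndarray, n_x: int) -> np.ndarray:
    """Counts of subsets of size ``n_x`` by rank-sum, over doubled midranks.

    Returns an array ``counts`` where ``counts[s]`` is the number of size-n_x
    subsets of the pooled doubled ranks summing to ``s``.  Doubling makes
    midranks integral so the DP is exact.
    """
    total = int(double_ranks.sum())
    table = np.zeros((n_x + 1, total + 1), dtype=np.int64)
    table[0, 0] = 1
    for r in double_ranks:
        r = int(r)
        # iterate sizes downwards so each item is used at most once
        for k in range(n_x, 0, -1):
            table[k, r:] += table[k - 1, : total + 1 - r]
    return table[n_x]


def rank_sum_greater(x, y, exact_max: int = EXACT_MAX) -> float:
    """One-sided rank-sum p-value for H1: values in ``x`` tend to be greater."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise GroupingError("rank-sum test requires both groups non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    t_x = ranks[: x.size].sum()
    has_ties = np.unique(pooled).size < pooled.size

    if x.size <= exact_max and y.size <= exact_max:
        double = np.rint(2 * ranks).astype(np.int64)
        counts = _exact_ranksum_distribution(double, x.size)
        total = counts.sum()
        t2 = int(round(2 * t_x))
        greater = counts[t2 + 1:].sum()
        equal = counts[t2]
        if has_ties:
            p = (greater + 0.5 * equal) / total
        else:
            p = (greater + equal) / total
        return float(p)

    # normal approximation with tie correction
    n, n1 = pooled.size, x.size
    n2 = y.size
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.5  # all values identical
    z = (t_x - mu) / np.sqrt(var)
    return float(stats.norm.sf(z))
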