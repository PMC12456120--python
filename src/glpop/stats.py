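"""Wilcoxon rank-sum test, self-contained.

Exact null distribution of the rank sum by the classic generating-
function DP when both samples have at most ``exact_max`` observations
and no ties are present; otherwise a normal approximation with tie
correction.  Two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first sample
    pvalue: float
    method: str  # "exact" or "normal"


def _exact_tail_counts(n: int, N: int) -> np.ndarray:
    """counts[s] = number of n-subsets of {1..N} with rank sum s."""
    max_sum = n * N
    counts = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(n, r), 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r else counts[k - 1, :]
    return counts[n]


def rank_sum_test(x, y, exact_max: int = 20) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of samples x and y.

    Exact when len(x) <= exact_max, len(y) <= exact_max and there are
    no tied values; otherwise normal approximation with tie-corrected
    variance (no continuity correction).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(n + m, dtype=np.float64)
    sorted_vals = combined[order]
    # midranks for ties
    i = 0
    while i < n + m:
        j = i
        while j + 1 < n + m and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    W = float(ranks[:n].sum())
    has_ties = len(np.unique(combined)) < n + m
    N = n + m
    if not has_ties and n <= exact_max and m <= exact_max:
        counts = _exact_tail_counts(n, N)
        total = counts.sum()
        w_int = int(round(W))
        p_le = counts[: w_int + 1].sum() / total
        p_ge = counts[w_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(W, p, "exact")
    mean = n * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1.0))
    var = n * m / 12.0 * ((N + 1.0) - tie_term)
    if var <= 0:
        return RankSumResult(W, 1.0, "normal")
    z = (W - mean) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return RankSumResult(W, p, "normal")
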