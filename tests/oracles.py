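"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def dp_optimal_kmeans_1d(values: np.ndarray, k: int) -> tuple[float, list[np.ndarray]]:
    """Exact optimal 1-D k-means by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the optimum
    is found over segment partitions with prefix-sum segment costs in
    O(k n^2).  Returns (optimal WCSS, list of member arrays).
    """
    xs = np.sort(np.asarray(values, dtype=float))
    n = len(xs)
    cum1 = np.concatenate([[0.0], np.cumsum(xs)])
    cum2 = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def seg_cost(i: int, j: int) -> float:
        # cost of xs[i:j] around its mean
        cnt = j - i
        s = cum1[j] - cum1[i]
        ss = cum2[j] - cum2[i]
        return ss - s * s / cnt

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for i in range(m - 1, j):
                c = dp[m - 1, i] + seg_cost(i, j)
                if c < dp[m, j]:
                    dp[m, j] = c
                    back[m, j] = i
    segments = []
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        segments.append(xs[i:j])
        j = i
    return float(dp[k, n]), segments[::-1]
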