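"""Independent oracles used by the tests.

These deliberately share no code with the package: exhaustive enumeration
and dynamic programming over contiguous partitions (optimal 1-D k-means
partitions are contiguous in sorted order), and brute-force statistics.
"""
from __future__ import annotations

import itertools

import numpy as np


def exhaustive_optimal_wss(values, k: int) -> float:
    """Global minimum within-cluster sum of squares by enumerating every
    contiguous split of the sorted values (exhaustive for 1-D)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        wss = 0.0
        for i in range(k):
            seg = x[bounds[i]:bounds[i + 1]]
            wss += ((seg - seg.mean()) ** 2).sum()
        best = min(best, wss)
    return float(best)


def dp_optimal_wss(values, k: int) -> float:
    """Optimal 1-D k-means WSS by dynamic programming over sorted prefixes."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:  # half-open [i, j)
        s = pre[j] - pre[i]
        s2 = pre2[j] - pre2[i]
        return s2 - s * s / (j - i)

    dp = np.full((k + 1, n + 1), np.inf)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            dp[kk, j] = min(
                dp[kk - 1, i] + seg_cost(i, j) for i in range(kk - 1, j)
            )
    return float(dp[k, n])


def silhouette_best_k(values, k_range) -> int:
    """Grid-search k maximising the mean silhouette of a k-means fit."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    best_k, best_s = None, -np.inf
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(x)
        s = silhouette_score(x, km.labels_)
        if s > best_s:
            best_k, best_s = k, s
    return best_k
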