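"""Independent brute-force oracles for the graph metrics.

Shortest paths by adjacency-matrix powers (d_ij = smallest m with
(A**m)_ij > 0), triangles by an explicit triple loop.  Deliberately naive
and separate from the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    power = np.eye(n, dtype=np.int64)
    for m in range(1, n):
        power = power @ a.astype(np.int64)
        newly = (power > 0) & np.isinf(d)
        d[newly] = m
    return d


def brute_mean_geodesic(a: np.ndarray) -> float:
    n = a.shape[0]
    d = brute_distances(a)
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    vals = [d[i, j] for i, j in off]
    if any(math.isinf(v) for v in vals):
        return math.inf
    return sum(vals) / (n * (n - 1))


def brute_global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    d = brute_distances(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and not math.isinf(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_clustering(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        k = int(a[i].sum())
        if k < 2:
            continue
        t = 0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    t += a[i, j] * a[j, h] * a[h, i]
        total += t / (k * (k - 1))  # t double-counts ordered (j, h) pairs
    return total / n


def brute_local_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        m = len(nbrs)
        if m < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = brute_distances(sub)
        s = 0.0
        for u in range(m):
            for v in range(m):
                if u != v and not math.isinf(d[u, v]):
                    s += 1.0 / d[u, v]
        total += s / (m * (m - 1))
    return total / n
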