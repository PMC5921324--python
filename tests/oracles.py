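"""Brute-force reference implementations, independent of the package.

These recompute clustering, path lengths, efficiencies and betweenness by
direct enumeration (neighbor-pair counting, Floyd-Warshall, shortest-path
counting by dynamic programming) so the package's vectorized/library-backed
implementations can be checked against them on small graphs.
"""

from __future__ import annotations

import numpy as np

INF = np.inf
_TOL = 1e-9


def oracle_clustering(adj: np.ndarray) -> np.ndarray:
    """Binary clustering by counting connected neighbor pairs per node."""
    n = adj.shape[0]
    a = adj > 0
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for x in range(k) for y in range(x + 1, k) if a[nbrs[x], nbrs[y]]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def oracle_clustering_onnela(adj: np.ndarray) -> np.ndarray:
    """Weighted (Onnela) clustering by explicit triangle enumeration."""
    n = adj.shape[0]
    wmax = adj.max()
    w = adj / wmax if wmax > 0 else adj
    a = adj > 0
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for x in range(k):
            for y in range(x + 1, k):
                j, h = nbrs[x], nbrs[y]
                if a[j, h]:
                    s += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * s / (k * (k - 1))
    return out


def oracle_distances(adj: np.ndarray, weighted: bool = False) -> np.ndarray:
    """All-pairs shortest paths by Floyd-Warshall (triple loop)."""
    n = adj.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i, j] > 0:
                d[i, j] = 1.0 / adj[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_lp(adj: np.ndarray, weighted: bool = False) -> float:
    """Mean distance over connected ordered pairs (finite-pair convention)."""
    d = oracle_distances(adj, weighted)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no connected pair")
    return float(np.mean(vals))


def oracle_efficiency(adj: np.ndarray, weighted: bool = False) -> float:
    d = oracle_distances(adj, weighted)
    n = d.shape[0]
    if n < 2:
        return 0.0
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def oracle_local_efficiency(adj: np.ndarray, weighted: bool = False) -> float:
    n = adj.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals[i] = oracle_efficiency(sub, weighted)
    return float(vals.mean())


def oracle_betweenness(adj: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Pair-fraction betweenness via distance + path-count DP (not Brandes).

    sigma(s, t) is accumulated by scanning targets in order of distance from
    s; node v gets sum over pairs s < t (v not an endpoint) of
    sigma_via_v / sigma(s, t).
    """
    n = adj.shape[0]
    d = oracle_distances(adj, weighted)
    # path counts
    sigma = np.zeros((n, n))
    for s in range(n):
        order = sorted(range(n), key=lambda t: d[s, t])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            cnt = 0.0
            for u in range(n):
                if adj[u, t] > 0:
                    w = 1.0 / adj[u, t] if weighted else 1.0
                    if abs(d[s, u] + w - d[s, t]) < _TOL:
                        cnt += sigma[s, u]
            sigma[s, t] = cnt
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < _TOL:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc
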