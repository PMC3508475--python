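"""Brute-force graph-metric oracles for small graphs.

Independent reference implementations used to validate the package's metric
functions: all-pairs BFS for distances, direct triangle enumeration for
clustering, shortest-path counting for betweenness, and pair counting for the
adjusted Rand index. Deliberately simple and slow; only for n <= ~10.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances; inf if unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in range(n):
                if adj[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = dist[s, u] + 1
                    queue.append(v)
    return dist


def brute_components(adj: np.ndarray) -> int:
    dist = bfs_distances(adj)
    n = adj.shape[0]
    seen: set[int] = set()
    count = 0
    for s in range(n):
        if s not in seen:
            count += 1
            seen.update(v for v in range(n) if dist[s, v] < np.inf)
    return count


def brute_cpl(adj: np.ndarray) -> float | None:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    pairs = [dist[i, j] for i in range(n) for j in range(i + 1, n)]
    if any(d == np.inf for d in pairs):
        return None
    return float(np.mean(pairs))


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    vals = [
        0.0 if dist[i, j] == np.inf else 1.0 / dist[i, j]
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals)) if vals else 0.0


def brute_regional_efficiency(adj: np.ndarray) -> list[float]:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    out = []
    for i in range(n):
        inv = [0.0 if dist[i, j] == np.inf else 1.0 / dist[i, j] for j in range(n) if j != i]
        out.append(float(np.mean(inv)) if inv else 0.0)
    return out


def brute_clustering(adj: np.ndarray) -> list[float]:
    """Binary clustering: closed neighbor pairs over all neighbor pairs."""
    n = adj.shape[0]
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        closed = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        out.append(closed / (k * (k - 1) / 2))
    return out


def brute_mean_clustering(adj: np.ndarray) -> float:
    return float(np.mean(brute_clustering(adj)))


def _path_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distance, number-of-shortest-paths) matrices by BFS counting."""
    n = adj.shape[0]
    dist = bfs_distances(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for d in range(1, n):
            for v in range(n):
                if dist[s, v] == d:
                    sigma[s, v] = sum(
                        sigma[s, u] for u in range(n) if adj[u, v] and dist[s, u] == d - 1
                    )
    return dist, sigma


def brute_betweenness(adj: np.ndarray) -> list[float]:
    """Normalized betweenness by explicit shortest-path counting."""
    n = adj.shape[0]
    dist, sigma = _path_counts(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if dist[s, t] == np.inf or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if dist[s, v] + dist[v, t] == dist[s, t]:
                bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2
    return (bc / norm).tolist() if norm > 0 else bc.tolist()


def brute_ari(labels_a, labels_b) -> float:
    """Hubert-Arabie ARI from explicit pair counting over all node pairs."""
    n = len(labels_a)
    same_a = same_b = both = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        a = labels_a[i] == labels_a[j]
        b = labels_b[i] == labels_b[j]
        same_a += a
        same_b += b
        both += a and b
    expected = same_a * same_b / pairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


def brute_best_modularity(adj: np.ndarray) -> float:
    """Exhaustive-search maximum Newman-Girvan modularity over all partitions."""
    n = adj.shape[0]
    m2 = adj.sum()  # 2m for binary symmetric
    degrees = adj.sum(axis=1)

    def q_of(labels) -> float:
        q = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += adj[i, j] - degrees[i] * degrees[j] / m2
        return q / m2

    best = -1.0
    for labels in _set_partitions(n):
        best = max(best, q_of(labels))
    return best


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label strings."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)
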