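"""Independent brute-force oracles used only by the test suite.

Each function recomputes a quantity by the most literal method available —
triple-loop dynamic programming, exhaustive path enumeration, direct
counting, truncated series — deliberately sharing no code with the
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

INF = float("inf")


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest directed distances by triple-loop DP."""
    n = adj.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and adj[s, t]:
                d[s, t] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def enumerate_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    """All shortest s→t paths by depth-limited DFS at the BFS distance."""
    d = floyd_warshall(adj)
    if not np.isfinite(d[s, t]) or s == t:
        return []
    limit = int(d[s, t])
    paths: list[list[int]] = []

    def walk(node: int, trail: list[int]) -> None:
        if len(trail) - 1 > limit:
            return
        if node == t and len(trail) - 1 == limit:
            paths.append(trail.copy())
            return
        for nxt in np.flatnonzero(adj[node]):
            if nxt not in trail:
                trail.append(int(nxt))
                walk(int(nxt), trail)
                trail.pop()

    walk(s, [s])
    return paths


def betweenness_by_enumeration(adj: np.ndarray) -> np.ndarray:
    """Fractional-count betweenness via explicit path enumeration,
    normalized by (N−1)(N−2).  Feasible for N ≤ 8."""
    n = adj.shape[0]
    b = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = enumerate_shortest_paths(adj, s, t)
            if not paths:
                continue
            for path in paths:
                for node in path[1:-1]:
                    b[node] += 1.0 / len(paths)
    return b / ((n - 1) * (n - 2))


def clustering_by_pairs(adj: np.ndarray) -> np.ndarray:
    """Directed union-neighbourhood clustering by explicit pair loops."""
    n = adj.shape[0]
    c = np.full(n, np.nan)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and (adj[i, j] or adj[j, i])]
        if len(nbrs) < 2:
            continue
        links = sum(
            1 for u in nbrs for v in nbrs if u != v and adj[u, v]
        )
        c[i] = links / (len(nbrs) * (len(nbrs) - 1))
    return c


def rich_club_by_counting(adj: np.ndarray, k: int) -> float:
    """Φ(k) by direct counting over nodes with total degree > k."""
    n = adj.shape[0]
    deg = [int(adj[i].sum() + adj[:, i].sum()) for i in range(n)]
    members = [i for i in range(n) if deg[i] > k]
    if len(members) < 2:
        return float("nan")
    edges = sum(1 for s in members for t in members if s != t and adj[s, t])
    return edges / (len(members) * (len(members) - 1))


def communicability_by_series(adj: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """exp(A) as the power series Σ A^n / n! truncated at tolerance."""
    a = adj.astype(float)
    term = np.eye(a.shape[0])
    total = term.copy()
    for n in range(1, 200):
        term = term @ a / n
        total += term
        if np.abs(term).max() < tol:
            break
    return total


def modularity_undirected(b: np.ndarray, labels: np.ndarray) -> float:
    """Textbook undirected Q from an explicit double loop."""
    two_m = b.sum()
    k = b.sum(axis=1)
    q = 0.0
    n = b.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += b[i, j] - k[i] * k[j] / two_m
    return q / two_m


def best_partition_exhaustive(b: np.ndarray) -> tuple[float, list[int]]:
    """Maximum-modularity partition by exhaustive search (N ≤ 8)."""
    n = b.shape[0]
    best_q, best_labels = -math.inf, [0] * n

    def assignments(i: int, labels: list[int], n_used: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(n_used + 1):
            labels.append(lab)
            yield from assignments(i + 1, labels, max(n_used, lab + 1))
            labels.pop()

    for labels in assignments(0, [], 0):
        q = modularity_undirected(b, np.array(labels))
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels
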