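"""Per-node and global binary network metrics, plus communicability.

All metrics operate on a square binary adjacency matrix in source→target
orientation (entry (s, t) = 1 iff there is a projection s→t).  Undefined
values — clustering of a node with fewer than two neighbours, path length of
a node that reaches nothing — are returned as NaN and excluded from means,
never silently zeroed.

Directed clustering here is the literal neighbourhood-density definition:
neighbours of i are the union of its in- and out-neighbours, the numerator
counts directed edges among them, and the denominator is n(n−1).  This is
deliberately not the Fagiolo triangle decomposition.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import networkx as nx
from scipy.linalg import expm
from scipy.sparse.csgraph import shortest_path


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency has nonzero diagonal (self-loops)")
    return (adj != 0).astype(np.int8)


def degrees(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(k_in, k_out, k_total) per node.

    Out-degree is the row sum (efferents of the source row), in-degree the
    column sum (afferents of the target column); total = in + out.
    """
    adj = _check_adjacency(adj)
    k_out = adj.sum(axis=1).astype(np.int64)
    k_in = adj.sum(axis=0).astype(np.int64)
    return k_in, k_out, k_in + k_out


def clustering_coefficient(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Directed clustering C_i per node and its mean C.

    C_i = (directed edges among the union of i's in/out-neighbours) /
    (n_nbr · (n_nbr − 1)).  Nodes with fewer than 2 neighbours get NaN and
    do not enter the mean.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    und = (adj | adj.T).astype(bool)
    c = np.full(n, np.nan)
    for i in range(n):
        nbrs = np.flatnonzero(und[i])
        m = len(nbrs)
        if m < 2:
            continue
        c[i] = adj[np.ix_(nbrs, nbrs)].sum() / (m * (m - 1))
    mean = float(np.nanmean(c)) if np.any(~np.isnan(c)) else float("nan")
    return c, mean


@dataclasses.dataclass(frozen=True)
class PathMetrics:
    """Directed shortest-path summary of a binary graph."""

    distances: np.ndarray        # (n, n) float, inf where unreachable
    L_i: np.ndarray              # per-node mean distance over reachable targets
    unreachable: np.ndarray      # per-node count of unreachable targets
    L: float                     # mean of defined L_i (characteristic path length)
    efficiency: float            # mean of 1/d over ordered pairs, 1/inf = 0
    diameter: float              # max finite off-diagonal distance


def path_lengths(adj: np.ndarray) -> PathMetrics:
    """BFS distances, per-node path length L_i, global L, efficiency, diameter.

    L_i averages over *reachable* targets only; the number of unreachable
    targets is reported per node rather than folded into the mean.  Global
    efficiency treats unreachable pairs as zero contribution, which is why it
    is the preferred global metric for sparse or fragmented subgraphs.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    if adj.sum() == 0:
        nanv = np.full(n, np.nan)
        return PathMetrics(
            distances=np.where(np.eye(n, dtype=bool), 0.0, np.inf),
            L_i=nanv, unreachable=np.full(n, n - 1, dtype=np.int64),
            L=float("nan"), efficiency=float("nan"), diameter=float("nan"),
        )
    d = shortest_path(adj, method="D", directed=True, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    L_i = np.full(n, np.nan)
    counts = finite.sum(axis=1)
    rows = counts > 0
    L_i[rows] = np.where(finite, d, 0.0).sum(axis=1)[rows] / counts[rows]
    unreachable = (n - 1) - counts
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    efficiency = float(inv[off].mean()) if n > 1 else float("nan")
    diameter = float(d[finite].max()) if finite.any() else float("nan")
    L = float(np.nanmean(L_i)) if rows.any() else float("nan")
    return PathMetrics(d, L_i, unreachable.astype(np.int64), L, efficiency, diameter)


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Directed shortest-path betweenness B_i, normalized by (N−1)(N−2).

    Equal-length shortest paths share credit fractionally (Brandes
    accumulation, as implemented in networkx for directed graphs).
    """
    adj = _check_adjacency(adj)
    g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    b = nx.betweenness_centrality(g, normalized=True)
    return np.array([b[i] for i in range(adj.shape[0])])


def communicability(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Communicability matrix exp(A) and the global mean.

    Entry (s, t) of exp(A) sums walks of every length from s to t weighted
    1/n!, so it rewards many short routes.  The global value is the mean of
    the off-diagonal entries of exp(A) − I (an empty graph scores 0); the
    local communicability of an edge s→t is simply entry (s, t).
    """
    adj = _check_adjacency(adj).astype(float)
    n = adj.shape[0]
    comm = expm(adj)
    off = ~np.eye(n, dtype=bool)
    global_comm = float(comm[off].mean()) if n > 1 else float("nan")
    return comm, global_comm


def out_in_ratio(adj: np.ndarray) -> np.ndarray:
    """k_out / k_in per node; NaN where k_in = 0."""
    k_in, k_out, _ = degrees(adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(k_in > 0, k_out / np.maximum(k_in, 1), np.nan)
    return ratio


def node_metrics_table(adj: np.ndarray, participation: np.ndarray | None = None):
    """Assemble the per-node metric table used by hub scoring and exports."""
    import pandas as pd

    k_in, k_out, k_total = degrees(adj)
    c_i, _ = clustering_coefficient(adj)
    pm = path_lengths(adj)
    df = pd.DataFrame(
        {
            "k_in": k_in,
            "k_out": k_out,
            "k_total": k_total,
            "C_i": c_i,
            "L_i": pm.L_i,
            "unreachable": pm.unreachable,
            "B_i": betweenness(adj),
            "out_in_ratio": out_in_ratio(adj),
        }
    )
    if participation is not None:
        df["P_i"] = participation
    return df


@dataclasses.dataclass(frozen=True)
class GlobalMetrics:
    density: float
    C: float
    L: float
    efficiency: float
    diameter: float
    communicability_global: float


def global_metrics(adj: np.ndarray) -> GlobalMetrics:
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    density = float(adj.sum() / (n * (n - 1))) if n > 1 else float("nan")
    _, c = clustering_coefficient(adj)
    pm = path_lengths(adj)
    _, gc = communicability(adj)
    return GlobalMetrics(density, c, pm.L, pm.efficiency, pm.diameter, gc)


def small_world(
    c_obs: float, l_obs: float, c_null: np.ndarray, l_null: np.ndarray
) -> tuple[float, float, float]:
    """Normalized clustering γ = C/⟨C_rand⟩, normalized path length
    λ = L/⟨L_rand⟩, and the small-world index γ/λ."""
    c_null = np.asarray(c_null, dtype=float)
    l_null = np.asarray(l_null, dtype=float)
    if c_null.size == 0 or l_null.size == 0:
        raise ValueError("null ensemble is empty")
    gamma = c_obs / float(np.nanmean(c_null))
    lam = l_obs / float(np.nanmean(l_null))
    return gamma, lam, gamma / lam


# ---------------------------------------------------------------------------
# Documented weighted variants (non-canonical; see docs/methods.md)
# ---------------------------------------------------------------------------

def weighted_clustering(adj: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted clustering variant with geometric-mean triangle weights.

    Each directed edge u→v inside node i's neighbourhood contributes
    (w̃_iu · ŵ_uv · w̃_iv)^(1/3), where ŵ is the weight scaled to [0, 1] by
    the maximum and w̃_ix is the symmetrized (max over the two directions)
    scaled weight between i and its neighbour; the denominator stays
    n_nbr(n_nbr−1).  The binary definition is the canonical one; this
    variant exists only to compute weighted/binary contrast ratios and is
    labelled as such.
    """
    adj = _check_adjacency(adj)
    w = np.asarray(weights, dtype=float)
    w = np.where((adj > 0) & (w > 0), w, 0.0)
    if w.max() > 0:
        w = w / w.max()
    w_sym = np.maximum(w, w.T)
    und = (adj | adj.T).astype(bool)
    n = adj.shape[0]
    c = np.full(n, np.nan)
    for i in range(n):
        nbrs = np.flatnonzero(und[i])
        m = len(nbrs)
        if m < 2:
            continue
        block = w[np.ix_(nbrs, nbrs)]                 # ŵ_uv among neighbours
        anchor = w_sym[i, nbrs]                        # w̃_iu per neighbour
        tri = np.cbrt(anchor[:, None] * block * anchor[None, :])
        c[i] = tri.sum() / (m * (m - 1))
    mean = float(np.nanmean(c)) if np.any(~np.isnan(c)) else float("nan")
    return c, mean


def weighted_path_lengths(adj: np.ndarray, weights: np.ndarray) -> PathMetrics:
    """Weighted path-length variant: edge length = 1/strength, Dijkstra
    distances; same averaging policy as :func:`path_lengths`.  Unknown-weight
    edges fall back to length 1 (the binary step)."""
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    w = np.asarray(weights, dtype=float)
    lengths = np.zeros((n, n))
    mask = adj > 0
    lengths[mask] = np.where(w[mask] > 0, 1.0 / np.maximum(w[mask], 1e-12), 1.0)
    if not mask.any():
        return path_lengths(adj)
    d = shortest_path(lengths, method="D", directed=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    L_i = np.full(n, np.nan)
    counts = finite.sum(axis=1)
    rows = counts > 0
    L_i[rows] = np.where(finite, d, 0.0).sum(axis=1)[rows] / counts[rows]
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    return PathMetrics(
        d, L_i, ((n - 1) - counts).astype(np.int64),
        float(np.nanmean(L_i)) if rows.any() else float("nan"),
        float(inv[off].mean()), float(d[finite].max()) if finite.any() else float("nan"),
    )
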