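"""Per-strength subgraphs and their topology profiles against matched nulls.

For each strength class w in 1..7 the subgraph A^w keeps exactly the edges
of strength w over the full node set.  Its clustering, modularity, global
efficiency and diameter are normalized by the means over degree-preserving
rewires of A^w itself — "randomized networks of equal density and equal
degree sequence" — so each class is judged against its own wiring budget.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import UNKNOWN, Connectome
from .community import modularity, newman_partition
from .metrics import clustering_coefficient, path_lengths
from .nulls import build_ensemble

WEIGHT_LEVELS = tuple(range(1, 8))


def weight_subgraph(c: Connectome, w: int) -> np.ndarray:
    """Binary adjacency of the strength-w subgraph A^w (all N nodes kept)."""
    if w not in WEIGHT_LEVELS:
        raise ValueError(f"strength class must be 1–7, got {w}")
    n = c.n_regions
    adj = np.zeros((n, n), dtype=np.int8)
    for s, t, strength in c.edges:
        if strength == w:
            adj[s, t] = 1
    return adj


def _subgraph_metrics(adj: np.ndarray) -> dict[str, float]:
    _, c_mean = clustering_coefficient(adj)
    pm = path_lengths(adj)
    part = newman_partition(adj)
    return {
        "C": c_mean,
        "Q": modularity(adj, part.assignment),
        "efficiency": pm.efficiency,
        "diameter": pm.diameter,
    }


@dataclasses.dataclass(frozen=True)
class WeightClassProfile:
    w: int
    edge_count: int
    share: float                  # fraction of all weighted edges
    density: float                # edge_count / (N (N − 1)), full node set
    n_active: int                 # nodes with at least one edge in A^w
    raw: dict[str, float]
    null_mean: dict[str, float]
    normalized: dict[str, float]  # raw / null mean
    insufficient: bool = False    # fewer than 3 non-isolated nodes

    def to_row(self) -> dict:
        row = {"w": self.w, "edge_count": self.edge_count, "share": self.share,
               "density": self.density, "n_active": self.n_active,
               "insufficient": self.insufficient}
        for name in ("C", "Q", "efficiency", "diameter"):
            row[name] = self.raw.get(name, np.nan)
            row[f"{name}_null"] = self.null_mean.get(name, np.nan)
            row[f"{name}_norm"] = self.normalized.get(name, np.nan)
        return row


def profile_weight_class(
    c: Connectome,
    w: int,
    n_null: int = 200,
    seed: int = 0,
    attempts_per_edge: int = 100,
) -> WeightClassProfile:
    """Topology profile of the strength-w subgraph, normalized by its nulls.

    Raw clustering C, modularity Q, global efficiency and diameter of A^w
    are each divided by their mean over ``n_null`` degree-preserving rewires
    of A^w.  Isolated nodes are excluded from C by the NaN policy of the
    metrics layer; diameter is the maximum over finite distances.  A profile
    over fewer than 3 connected nodes is flagged insufficient.
    """
    adj = weight_subgraph(c, w)
    n = c.n_regions
    n_weighted = sum(1 for _, _, s in c.edges if s != UNKNOWN)
    edge_count = int(adj.sum())
    active = int(((adj.sum(axis=0) + adj.sum(axis=1)) > 0).sum())
    base = {
        "w": w,
        "edge_count": edge_count,
        "share": edge_count / n_weighted if n_weighted else float("nan"),
        "density": edge_count / (n * (n - 1)),
        "n_active": active,
    }
    if active < 3:
        return WeightClassProfile(**base, raw={}, null_mean={}, normalized={},
                                  insufficient=True)
    raw = _subgraph_metrics(adj)
    ens = build_ensemble(
        adj, {"all": lambda a: np.array(list(_subgraph_metrics(a).values()))},
        n_null=n_null, seed=seed, attempts_per_edge=attempts_per_edge,
    )
    names = list(raw)
    null_matrix = np.asarray(ens.metric_distributions["all"], dtype=float)
    null_mean = {name: float(np.nanmean(null_matrix[:, i]))
                 for i, name in enumerate(names)}
    normalized = {
        name: raw[name] / null_mean[name] if null_mean[name] else float("nan")
        for name in names
    }
    return WeightClassProfile(**base, raw=raw, null_mean=null_mean,
                              normalized=normalized)


def profile_all_classes(
    c: Connectome, n_null: int = 200, seed: int = 0,
    attempts_per_edge: int = 100,
) -> pd.DataFrame:
    """One profile row per strength class 1..7 (independent null seeds)."""
    rows = []
    for w in WEIGHT_LEVELS:
        prof = profile_weight_class(
            c, w, n_null=n_null, seed=seed + w, attempts_per_edge=attempts_per_edge
        )
        rows.append(prof.to_row())
    return pd.DataFrame(rows)
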