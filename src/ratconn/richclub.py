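"""Rich-club curve and significance, cumulative hub scoring, hub-set density.

The rich-club coefficient Φ(k) is the directed density of the subgraph
induced by nodes whose combined in- + out-degree strictly exceeds k.  Its
normalization Φ_norm(k) = Φ(k)/⟨Φ_random(k)⟩ uses degree-preserving rewired
nulls, which share the observed graph's degree sequence and hence its k
grid.  Hubs are selected by a cumulative score counting appearances in the
top tier of five nodal centrality rankings.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .nulls import NullEnsemble, empirical_p


@dataclasses.dataclass(frozen=True)
class RichClubCurve:
    k: np.ndarray                 # degree thresholds with N_>k >= 2
    n_gt_k: np.ndarray            # nodes with total degree > k
    e_gt_k: np.ndarray            # directed edges among them
    phi: np.ndarray               # E_>k / (N_>k (N_>k − 1))
    phi_random_mean: np.ndarray | None = None
    phi_norm: np.ndarray | None = None
    p: np.ndarray | None = None

    def significant_range(self, alpha: float = 0.01) -> tuple[int, int] | None:
        """Longest contiguous run of k with p < alpha (ties → highest k)."""
        if self.p is None:
            raise ValueError("curve has no p-values; run rich_club_significance")
        sig = self.p < alpha
        best: tuple[int, int] | None = None
        start = None
        for i, flag in enumerate([*sig, False]):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                run = (int(self.k[start]), int(self.k[i - 1]))
                if best is None or (run[1] - run[0]) >= (best[1] - best[0]):
                    best = run
                start = None
        return best

    def to_frame(self) -> pd.DataFrame:
        data = {"k": self.k, "N_gt_k": self.n_gt_k, "E_gt_k": self.e_gt_k,
                "phi": self.phi}
        if self.phi_random_mean is not None:
            data.update(phi_random_mean=self.phi_random_mean,
                        phi_norm=self.phi_norm, p=self.p)
        return pd.DataFrame(data)


def _phi_at(adj: np.ndarray, k_total: np.ndarray, k: int) -> tuple[int, int, float]:
    members = np.flatnonzero(k_total > k)
    n = members.size
    if n < 2:
        return n, 0, float("nan")
    e = int(adj[np.ix_(members, members)].sum())
    return n, e, e / (n * (n - 1))


def rich_club_curve(adj: np.ndarray) -> RichClubCurve:
    """Φ(k) for k = 0 .. max(k_total) − 1, reported where N_>k ≥ 2."""
    adj = (np.asarray(adj) != 0).astype(np.int64)
    k_total = adj.sum(axis=0) + adj.sum(axis=1)
    ks, ns, es, phis = [], [], [], []
    for k in range(int(k_total.max(initial=0))):
        n, e, phi = _phi_at(adj, k_total, k)
        if n >= 2:
            ks.append(k); ns.append(n); es.append(e); phis.append(phi)
    return RichClubCurve(
        k=np.asarray(ks, dtype=np.int64),
        n_gt_k=np.asarray(ns, dtype=np.int64),
        e_gt_k=np.asarray(es, dtype=np.int64),
        phi=np.asarray(phis, dtype=float),
    )


def phi_vector(adj: np.ndarray, k_grid: np.ndarray) -> np.ndarray:
    """Φ evaluated on a fixed k grid (NaN where N_>k < 2); the ensemble
    metric matching :func:`rich_club_curve`'s grid."""
    adj = (np.asarray(adj) != 0).astype(np.int64)
    k_total = adj.sum(axis=0) + adj.sum(axis=1)
    return np.asarray([_phi_at(adj, k_total, int(k))[2] for k in k_grid])


def rich_club_significance(
    adj: np.ndarray, ensemble: NullEnsemble, metric: str = "phi",
    p_rule: str = "add_one",
) -> RichClubCurve:
    """Complete rich-club curve: Φ, ⟨Φ_random⟩, Φ_norm and per-k empirical p.

    The ensemble must carry a vector-valued metric evaluated on this graph's
    own k grid (see :func:`phi_vector`); degree preservation guarantees the
    null graphs share that grid.
    """
    curve = rich_club_curve(adj)
    null_phi = np.asarray(ensemble.metric_distributions[metric], dtype=float)
    if null_phi.ndim != 2 or null_phi.shape[1] != curve.k.size:
        raise ValueError(
            f"ensemble metric {metric!r} has shape {null_phi.shape}, "
            f"expected (n_null, {curve.k.size}) — k grids mismatched"
        )
    mean = np.nanmean(null_phi, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = curve.phi / mean
    p = np.array([
        empirical_p(curve.phi[i], null_phi[:, i], side="greater", rule=p_rule)
        if not np.isnan(curve.phi[i]) else np.nan
        for i in range(curve.k.size)
    ])
    return RichClubCurve(curve.k, curve.n_gt_k, curve.e_gt_k, curve.phi,
                         mean, norm, p)


# ---------------------------------------------------------------------------
# Hub scoring
# ---------------------------------------------------------------------------

#: The five centrality criteria: (column, higher-is-more-central)
HUB_CRITERIA: tuple[tuple[str, bool], ...] = (
    ("k_in", True),
    ("k_out", True),
    ("B_i", True),
    ("P_i", True),
    ("L_i", False),   # short path length is central
)


def _top_tier(values: np.ndarray, descending: bool, m: int) -> np.ndarray:
    """Boolean membership of the top-m tier, ties at the boundary included;
    NaN ranks last."""
    v = np.asarray(values, dtype=float)
    filler = -np.inf if descending else np.inf
    v = np.where(np.isnan(v), filler, v)
    order = np.sort(v)[::-1] if descending else np.sort(v)
    cutoff = order[m - 1]
    return (v >= cutoff) if descending else (v <= cutoff)


def hub_scores(
    metrics: pd.DataFrame, top_fraction: float = 0.33
) -> pd.DataFrame:
    """Cumulative hub score 0–5 per node.

    One point for ranking in the top ``⌈top_fraction·N⌉`` on each of
    in-degree, out-degree, betweenness and participation (descending) and on
    path length L_i (ascending).  Boundary ties are all included.  A node is
    a hub when its score is ≥ 4.
    """
    missing = [col for col, _ in HUB_CRITERIA if col not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    n = len(metrics)
    m = max(1, math.ceil(top_fraction * n))
    out = pd.DataFrame(index=metrics.index)
    for col, descending in HUB_CRITERIA:
        out[f"top_{col}"] = _top_tier(metrics[col].to_numpy(), descending, m)
    out["score"] = out[[f"top_{c}" for c, _ in HUB_CRITERIA]].sum(axis=1)
    out["is_hub"] = out["score"] >= 4
    return out


def hub_set_rich_club(
    adj: np.ndarray, hubs: np.ndarray, ensemble: NullEnsemble,
    metric: str = "phi_H", p_rule: str = "add_one",
) -> tuple[float, float, float]:
    """Density Φ(H) of the hub set and its empirical p against nulls.

    The same node-index set H is evaluated in every null graph (the metric
    must have been registered on the ensemble via :func:`hub_phi_metric`).
    Returns (Φ_H, ⟨Φ_H,random⟩, p).
    """
    hubs = np.asarray(hubs)
    if hubs.size < 2:
        raise ValueError("hub set must contain at least 2 nodes")
    adj = (np.asarray(adj) != 0).astype(np.int64)
    h = hubs.size
    phi_h = float(adj[np.ix_(hubs, hubs)].sum() / (h * (h - 1)))
    null_vals = np.asarray(ensemble.metric_distributions[metric], dtype=float)
    p = empirical_p(phi_h, null_vals, side="greater", rule=p_rule)
    return phi_h, float(np.nanmean(null_vals)), p


def hub_phi_metric(hubs: np.ndarray):
    """Ensemble metric closure: density among a fixed node set."""
    hubs = np.asarray(hubs)
    h = hubs.size

    def phi_h(adj: np.ndarray) -> float:
        return float(np.asarray(adj)[np.ix_(hubs, hubs)].sum() / (h * (h - 1)))

    return phi_h
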