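"""Edge classification and edge-level measures.

Edges are cross-classified by the hub status of their endpoints (rich club /
feeder-in / feeder-out / local), by module membership (intra / inter), and by
reciprocity (bidirectional / unidirectional).  On top of that sit per-edge
measures — Euclidean projection distance, wiring cost (distance × strength),
edge module diversity — node-level degree-ratio and strength-ratio analyses,
and the single-edge-removal perturbation scan.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import UNKNOWN, Connectome, binary_adjacency
from .community import ModulePartition
from .metrics import clustering_coefficient, communicability, path_lengths
from .stats import PermutationResult, permutation_test, pearson_r

EDGE_CLASSES = ("rich_club", "feeder_out", "feeder_in", "local")

#: Strength thresholds for "strong" / "very strong" edges.
STRONG_MIN = 6
VERY_STRONG = 7


def classify_edges(
    c: Connectome, hubs: np.ndarray, partition: ModulePartition
) -> pd.DataFrame:
    """Per-edge class table.

    clazz: rich_club (hub→hub), feeder_out (hub→non-hub), feeder_in
    (non-hub→hub), local (non-hub→non-hub); modular: intra if both endpoints
    share a module; bidirectional iff the reverse edge exists.
    """
    hub_mask = np.zeros(c.n_regions, dtype=bool)
    hub_mask[np.asarray(hubs, dtype=int)] = True
    labels = partition.assignment
    if labels.shape[0] != c.n_regions:
        raise ValueError("partition does not cover the connectome's nodes")
    pairs = {(s, t) for s, t, _ in c.edges}
    rows = []
    for s, t, w in c.edges:
        if hub_mask[s] and hub_mask[t]:
            clazz = "rich_club"
        elif hub_mask[s]:
            clazz = "feeder_out"
        elif hub_mask[t]:
            clazz = "feeder_in"
        else:
            clazz = "local"
        rows.append(
            {
                "source": s,
                "target": t,
                "strength": w if w != UNKNOWN else np.nan,
                "clazz": clazz,
                "modular": "intra" if labels[s] == labels[t] else "inter",
                "bidirectional": (t, s) in pairs,
            }
        )
    return pd.DataFrame(rows)


def class_shares(records: pd.DataFrame) -> pd.DataFrame:
    """Edge-class shares plus the intra/inter cross-tabulation."""
    total = len(records)
    out = []
    for clazz in EDGE_CLASSES:
        sub = records[records["clazz"] == clazz]
        out.append(
            {
                "clazz": clazz,
                "count": len(sub),
                "share": len(sub) / total if total else np.nan,
                "intra_fraction": (sub["modular"] == "intra").mean() if len(sub) else np.nan,
                "bidirectional_fraction": sub["bidirectional"].mean() if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(out)


def edge_distances(
    c: Connectome, records: pd.DataFrame, decile: float = 0.10
) -> tuple[pd.DataFrame, dict]:
    """Euclidean projection distances, decile strength contrast, and the
    distance–strength correlation.

    Adds a ``distance`` column; the summary reports mean strength of the
    shortest and longest ``decile`` of edges and Pearson r(distance,
    strength) over weighted edges.  Requires region coordinates.
    """
    if c.regions.coords is None:
        raise ValueError("region coordinates are required for distance analyses")
    coords = c.regions.coords
    records = records.copy()
    d = np.linalg.norm(
        coords[records["source"].to_numpy()] - coords[records["target"].to_numpy()],
        axis=1,
    )
    records["distance"] = d
    weighted = records.dropna(subset=["strength"])
    summary: dict = {}
    if np.ptp(d) == 0 or len(weighted) < 3:
        summary["correlation"] = None  # degenerate geometry / too few edges
    else:
        n_dec = max(1, int(round(decile * len(weighted))))
        by_dist = weighted.sort_values("distance")
        summary["short_decile_mean_strength"] = float(
            by_dist.head(n_dec)["strength"].mean()
        )
        summary["long_decile_mean_strength"] = float(
            by_dist.tail(n_dec)["strength"].mean()
        )
        r, p = pearson_r(weighted["distance"], weighted["strength"])
        summary["correlation"] = {"r": r, "p": p, "n": len(weighted)}
    summary["class_mean_distance"] = {
        clazz: float(records.loc[records["clazz"] == clazz, "distance"].mean())
        for clazz in EDGE_CLASSES
    }
    return records, summary


def wiring_cost(
    records: pd.DataFrame, n_perm: int = 10_000, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, PermutationResult]]:
    """Cost = distance × strength per weighted edge, with class contrasts.

    Returns the table with a ``cost`` column and permutation contrasts of
    rich-club cost against each other class.
    """
    if "distance" not in records.columns:
        raise ValueError("distances missing; run edge_distances first")
    records = records.copy()
    records["cost"] = records["distance"] * records["strength"]
    contrasts: dict[str, PermutationResult] = {}
    rc = records.loc[records["clazz"] == "rich_club", "cost"].dropna()
    for i, other in enumerate(("local", "feeder_out", "feeder_in")):
        vals = records.loc[records["clazz"] == other, "cost"].dropna()
        if len(rc) and len(vals):
            contrasts[f"rich_club_vs_{other}"] = permutation_test(
                rc, vals, n_perm=n_perm, seed=seed + i
            )
    return records, contrasts


def edge_module_diversity(
    records: pd.DataFrame, p_node: np.ndarray
) -> pd.DataFrame:
    """EMD of each edge: the product p_i·p_j of its endpoints' module
    diversities."""
    records = records.copy()
    p_node = np.asarray(p_node, dtype=float)
    records["emd"] = (
        p_node[records["source"].to_numpy()] * p_node[records["target"].to_numpy()]
    )
    return records


# ---------------------------------------------------------------------------
# Node-level ratio analyses
# ---------------------------------------------------------------------------

SINK_MAX = 0.5    # out/in ratio below → neural sink
SOURCE_MIN = 1.5  # out/in ratio above → neural source


def degree_ratio_analysis(metrics: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Out/in-degree ratios, sink/source roles, and the ratio–degree relation.

    Nodes with k_in = 0 have an undefined ratio; they are excluded from the
    correlation and the balance fraction, and reported.
    """
    ratio = metrics["out_in_ratio"].to_numpy(dtype=float)
    roles = np.where(
        np.isnan(ratio), "undefined",
        np.where(ratio < SINK_MAX, "sink",
                 np.where(ratio > SOURCE_MIN, "source", "balanced")),
    )
    table = pd.DataFrame(
        {"out_in_ratio": ratio, "role": roles, "k_total": metrics["k_total"]}
    )
    defined = ~np.isnan(ratio)
    summary: dict = {
        "n_undefined": int((~defined).sum()),
        "n_sinks": int((roles == "sink").sum()),
        "n_sources": int((roles == "source").sum()),
        "balanced_fraction": float(
            ((ratio[defined] >= SINK_MAX) & (ratio[defined] <= SOURCE_MIN)).mean()
        ) if defined.any() else np.nan,
    }
    if defined.sum() >= 3:
        r, p = pearson_r(ratio[defined], metrics["k_total"].to_numpy()[defined])
        summary["ratio_vs_degree"] = {"r": r, "p": p}
    return table, summary


HL_THRESHOLD = 4  # strength > 4 counts high, <= 4 counts low


def hl_ratio(c: Connectome) -> np.ndarray:
    """Per-node ratio of high-strength (>4) to low-strength (≤4) edges.

    Both afferent and efferent weighted edges count, so an edge contributes
    to both endpoints.  Nodes with no low-strength edge get inf (flagged);
    nodes with no weighted edge at all get NaN.
    """
    high = np.zeros(c.n_regions)
    low = np.zeros(c.n_regions)
    for s, t, w in c.edges:
        if w == UNKNOWN:
            continue
        bucket = high if w > HL_THRESHOLD else low
        bucket[s] += 1
        bucket[t] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        hl = high / low
    hl[(high == 0) & (low == 0)] = np.nan
    return hl


def hl_ratio_analysis(c: Connectome, metrics: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """HL ratio per node plus its correlations with degree and 1/L_i.

    Infinite ratios (no low-strength edges) are excluded from the
    correlations and counted in the summary.
    """
    hl = hl_ratio(c)
    finite = np.isfinite(hl)
    summary: dict = {"n_infinite": int(np.isinf(hl).sum()),
                     "n_undefined": int(np.isnan(hl).sum())}
    k_total = metrics["k_total"].to_numpy(dtype=float)
    l_i = metrics["L_i"].to_numpy(dtype=float)
    if finite.sum() >= 3:
        r, p = pearson_r(hl[finite], k_total[finite])
        summary["hl_vs_degree"] = {"r": r, "p": p}
        with np.errstate(divide="ignore"):
            inv_l = 1.0 / l_i
        ok = finite & np.isfinite(inv_l)
        if ok.sum() >= 3:
            r2, p2 = pearson_r(hl[ok], inv_l[ok])
            summary["hl_vs_inverse_L"] = {"r": r2, "p": p2}
    return hl, summary


# ---------------------------------------------------------------------------
# Edge perturbation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PerturbationBaseline:
    L: float
    C: float
    comm_global: float
    comm_matrix: np.ndarray


def edge_perturbation(c: Connectome, progress: bool = False) -> pd.DataFrame:
    """Single-edge-removal impact scan on the binary network.

    For each edge, the edge alone is removed and the percentage change
    100·(after − before)/before is reported for: characteristic path length
    L, mean clustering C, global communicability, and the local
    communicability between the edge's endpoints (entry (s, t) of exp(A)).
    Weights play no role here beyond downstream binning.
    """
    adj = binary_adjacency(c).astype(float)
    base_pm = path_lengths(adj)
    _, base_c = clustering_coefficient(adj)
    base_comm, base_gc = communicability(adj)
    if not np.isfinite(base_pm.L):
        raise ValueError("path length undefined on the intact network")

    rows = []
    for s, t, w in c.edges:
        adj[s, t] = 0.0
        pm = path_lengths(adj)
        _, c_after = clustering_coefficient(adj)
        comm, gc = communicability(adj)
        adj[s, t] = 1.0
        rows.append(
            {
                "source": s,
                "target": t,
                "strength": w if w != UNKNOWN else np.nan,
                "dL_pct": 100.0 * (pm.L - base_pm.L) / base_pm.L,
                "dC_pct": 100.0 * (c_after - base_c) / base_c,
                "dcomm_global_pct": 100.0 * (gc - base_gc) / base_gc,
                "dcomm_local_pct": 100.0 * (comm[s, t] - base_comm[s, t])
                / base_comm[s, t],
                "disconnects": bool(pm.unreachable.sum() > base_pm.unreachable.sum()),
            }
        )
    return pd.DataFrame(rows)


def perturbation_class_summary(
    perturb: pd.DataFrame, records: pd.DataFrame
) -> pd.DataFrame:
    """Mean impact per edge class and per weight class.

    Joins the perturbation scan with the classification table on
    (source, target) and averages each impact column within groups.
    """
    merged = perturb.merge(
        records[["source", "target", "clazz", "modular"]],
        on=["source", "target"], how="left",
    )
    impact_cols = ["dL_pct", "dC_pct", "dcomm_global_pct", "dcomm_local_pct"]
    pieces = []
    for key in ("clazz", "modular"):
        grp = merged.groupby(key)[impact_cols].mean().reset_index()
        grp.insert(0, "grouping", key)
        grp = grp.rename(columns={key: "group"})
        pieces.append(grp)
    weighted = merged.dropna(subset=["strength"]).copy()
    weighted["weight_class"] = weighted["strength"].astype(int).astype(str)
    grp = weighted.groupby("weight_class")[impact_cols].mean().reset_index()
    grp.insert(0, "grouping", "weight_class")
    grp = grp.rename(columns={"weight_class": "group"})
    pieces.append(grp)
    return pd.concat(pieces, ignore_index=True)
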