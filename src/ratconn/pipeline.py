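"""End-to-end analysis pipeline: descriptives, nulls, communities, rich
club, edge classes, perturbation, weight-class profiles, and the
statistical contrasts between them — emitted as one structured report.

Stage order: load → filter → node/global metrics → community detection →
participation → hub scoring → null ensemble (shared by small-world,
normalized Q, rich-club curve and hub-set density) → edge classification
and edge measures → perturbation scan → per-weight-class profiles →
permutation contrasts.  Every number in the report is regenerable from the
inputs, the configuration and the seeds it records.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd

from . import community as comm
from . import edges as edgemod
from . import metrics as met
from . import nulls as nullmod
from . import richclub as rc
from . import weights as wmod
from .io import Connectome, binary_adjacency, filter_disconnected, weight_matrix
from .stats import permutation_test

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Tunable sizes of the inferential machinery.

    ``full`` fidelity uses 1,000 rewired nulls and 10,000 permutations;
    ``fast`` trades precision for runtime and is meant for tests and
    exploratory runs.
    """

    n_null: int = 1000
    n_perm: int = 10_000
    weight_class_nulls: int = 200
    attempts_per_edge: int = 100
    top_fraction: float = 0.33
    p_rule: str = "add_one"
    rich_club_alpha: float = 0.01
    seed: int = 0
    run_perturbation: bool = True

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "PipelineConfig":
        if name == "full":
            return cls(seed=seed)
        if name == "fast":
            return cls(n_null=100, n_perm=1000, weight_class_nulls=50, seed=seed)
        raise ValueError(f"unknown preset {name!r} (use 'full' or 'fast')")


def _json_safe(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _json_safe(dataclasses.asdict(obj))
    return obj


def _perm_summary(result) -> dict:
    return {
        "mean_a": result.mean_a, "mean_b": result.mean_b,
        "ratio": result.ratio, "observed_diff": result.observed_diff,
        "p": result.p, "n_perm": result.n_perm, "side": result.side,
    }


def run_full_analysis(
    c: Connectome,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the complete analysis and return the report dictionary.

    Distance and wiring-cost sections require region coordinates and are
    marked ``skipped`` when the region table has none.
    """
    config = config or PipelineConfig()
    rng_seed = config.seed
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
    }

    # --- load & filter ----------------------------------------------------
    filtered, removed = filter_disconnected(c)
    adj = binary_adjacency(filtered)
    w_matrix, n_weighted, weighted_fraction = weight_matrix(filtered)
    report["network"] = {
        "n_regions_input": c.n_regions,
        "n_removed": len(removed),
        "removed_regions": [c.regions.abbreviations[i] for i in removed],
        "n_regions": filtered.n_regions,
        "n_edges": filtered.n_edges,
        "density": filtered.density,
        "n_weighted_edges": n_weighted,
        "weighted_fraction": weighted_fraction,
        "n_unknown_strength": filtered.n_edges - n_weighted,
    }

    # --- node & global metrics -------------------------------------------
    gm = met.global_metrics(adj)

    # --- community structure ---------------------------------------------
    top, level2 = comm.hierarchical_partition(adj, seed=rng_seed)
    participation = comm.participation_coefficient(adj, top)
    diversity = comm.module_diversity(adj, top)
    node_table = met.node_metrics_table(adj, participation=participation)
    node_table["p_diversity"] = diversity
    report["partition"] = {
        "n_modules": top.n_modules,
        "Q": top.Q,
        "n_submodules": level2.n_modules,
        "Q_level2": level2.Q,
        "submodule_counts": comm.submodule_counts(top, level2),
        "assignment": top.assignment,
        "assignment_level2": level2.assignment,
    }

    # --- hub scoring ------------------------------------------------------
    hubs_table = rc.hub_scores(node_table, top_fraction=config.top_fraction)
    hub_ids = np.flatnonzero(hubs_table["is_hub"].to_numpy())
    report["hubs"] = {
        "n_hubs": int(hub_ids.size),
        "hub_ids": hub_ids,
        "hub_abbreviations": [filtered.regions.abbreviations[i] for i in hub_ids],
        "scores": hubs_table["score"].to_numpy(),
    }

    # --- null ensemble (one pass for all normalized metrics) --------------
    base_curve = rc.rich_club_curve(adj)
    k_grid = base_curve.k
    ensemble_metrics = {
        "C": lambda a: met.clustering_coefficient(a)[1],
        "L": lambda a: met.path_lengths(a).L,
        "Q": lambda a: comm.newman_partition(a).Q,
        "phi": lambda a: rc.phi_vector(a, k_grid),
    }
    if hub_ids.size >= 2:
        ensemble_metrics["phi_H"] = rc.hub_phi_metric(hub_ids)
    ensemble = nullmod.build_ensemble(
        adj, ensemble_metrics, n_null=config.n_null, seed=rng_seed,
        attempts_per_edge=config.attempts_per_edge,
    )
    gamma, lam, sw = met.small_world(
        gm.C, gm.L,
        ensemble.metric_distributions["C"], ensemble.metric_distributions["L"],
    )
    q_null = float(np.nanmean(ensemble.metric_distributions["Q"]))
    report["global_metrics"] = {
        "density": gm.density, "C": gm.C, "L": gm.L,
        "efficiency": gm.efficiency, "diameter": gm.diameter,
        "communicability_global": gm.communicability_global,
        "gamma": gamma, "lambda": lam, "small_world": sw,
        "Q_norm": top.Q / q_null if q_null else None,
        "n_null": config.n_null,
    }

    # --- rich club --------------------------------------------------------
    curve = rc.rich_club_significance(adj, ensemble, p_rule=config.p_rule)
    sig_range = curve.significant_range(config.rich_club_alpha)
    rich_block: dict[str, Any] = {
        "k": curve.k, "phi": curve.phi, "phi_norm": curve.phi_norm,
        "p": curve.p, "significant_range": sig_range,
        "min_p": float(np.nanmin(curve.p)) if curve.p is not None else None,
    }
    if hub_ids.size >= 2:
        phi_h, phi_h_null, p_h = rc.hub_set_rich_club(adj, hub_ids, ensemble,
                                                      p_rule=config.p_rule)
        rich_block["hub_set"] = {
            "phi_H": phi_h, "phi_H_random_mean": phi_h_null, "p": p_h,
            "phi_H_norm": phi_h / phi_h_null if phi_h_null else None,
        }
    report["rich_club"] = rich_block

    # --- edge classes and edge measures ----------------------------------
    records = edgemod.classify_edges(filtered, hub_ids, top)
    shares = edgemod.class_shares(records)
    report["edge_classes"] = {
        "shares": shares.to_dict(orient="records"),
        "bidirectional_fraction": float(records["bidirectional"].mean()),
        "intra_fraction": float((records["modular"] == "intra").mean()),
    }

    records = edgemod.edge_module_diversity(records, diversity)

    if filtered.regions.coords is not None:
        records, dist_summary = edgemod.edge_distances(filtered, records)
        records, cost_contrasts = edgemod.wiring_cost(
            records, n_perm=config.n_perm, seed=rng_seed + 11,
        )
        report["distances"] = dist_summary
        report["wiring_cost"] = {
            name: _perm_summary(result) for name, result in cost_contrasts.items()
        }
    else:
        report["distances"] = {"skipped": "no region coordinates"}
        report["wiring_cost"] = {"skipped": "no region coordinates"}

    ratio_table, ratio_summary = edgemod.degree_ratio_analysis(node_table)
    report["degree_ratio"] = ratio_summary
    hl, hl_summary = edgemod.hl_ratio_analysis(filtered, node_table)
    report["hl_ratio"] = hl_summary

    # --- statistical contrasts -------------------------------------------
    contrasts: dict[str, dict] = {}
    hub_mask = np.zeros(filtered.n_regions, dtype=bool)
    hub_mask[hub_ids] = True
    p_vals = node_table["P_i"].to_numpy(dtype=float)
    if hub_ids.size and (~hub_mask).any():
        contrasts["participation_hub_vs_peripheral"] = _perm_summary(
            permutation_test(p_vals[hub_mask], p_vals[~hub_mask],
                             n_perm=config.n_perm, seed=rng_seed + 21)
        )
    weighted = records.dropna(subset=["strength"])
    by_class = {cl: weighted.loc[weighted["clazz"] == cl, "strength"]
                for cl in edgemod.EDGE_CLASSES}
    for i, other in enumerate(("local", "feeder_out", "feeder_in")):
        if len(by_class["rich_club"]) and len(by_class[other]):
            contrasts[f"strength_rich_club_vs_{other}"] = _perm_summary(
                permutation_test(by_class["rich_club"], by_class[other],
                                 n_perm=config.n_perm, seed=rng_seed + 31 + i)
            )
    intra = weighted.loc[weighted["modular"] == "intra", "strength"]
    inter = weighted.loc[weighted["modular"] == "inter", "strength"]
    if len(intra) and len(inter):
        contrasts["strength_intra_vs_inter"] = _perm_summary(
            permutation_test(intra, inter, n_perm=config.n_perm,
                             seed=rng_seed + 41)
        )
    emd_rc = records.loc[records["clazz"] == "rich_club", "emd"]
    emd_local = records.loc[records["clazz"] == "local", "emd"]
    if len(emd_rc) and len(emd_local):
        contrasts["emd_rich_club_vs_local"] = _perm_summary(
            permutation_test(emd_rc, emd_local, n_perm=config.n_perm,
                             seed=rng_seed + 51)
        )

    # --- edge perturbation ------------------------------------------------
    if config.run_perturbation:
        perturb = edgemod.edge_perturbation(filtered)
        summary = edgemod.perturbation_class_summary(perturb, records)
        report["perturbation"] = {
            "class_summary": summary.to_dict(orient="records"),
        }
        merged = perturb.merge(records[["source", "target", "clazz", "modular"]],
                               on=["source", "target"])
        strong = merged.loc[merged["strength"] >= 6, "dcomm_global_pct"]
        weak = merged.loc[merged["strength"].isin([2, 3]), "dcomm_global_pct"]
        if len(strong) and len(weak):
            contrasts["perturbation_comm_strong_vs_weak"] = _perm_summary(
                permutation_test(strong.abs(), weak.abs(),
                                 n_perm=config.n_perm, seed=rng_seed + 61)
            )
        rc_imp = merged.loc[merged["clazz"] == "rich_club", "dcomm_global_pct"]
        local_imp = merged.loc[merged["clazz"] == "local", "dcomm_global_pct"]
        if len(rc_imp) and len(local_imp):
            contrasts["perturbation_comm_rich_club_vs_local"] = _perm_summary(
                permutation_test(rc_imp.abs(), local_imp.abs(),
                                 n_perm=config.n_perm, seed=rng_seed + 71)
            )
        inter_imp = merged.loc[merged["modular"] == "inter", "dcomm_global_pct"]
        intra_imp = merged.loc[merged["modular"] == "intra", "dcomm_global_pct"]
        if len(inter_imp) and len(intra_imp):
            contrasts["perturbation_comm_inter_vs_intra"] = _perm_summary(
                permutation_test(inter_imp.abs(), intra_imp.abs(),
                                 n_perm=config.n_perm, seed=rng_seed + 81)
            )
    else:
        report["perturbation"] = {"skipped": "disabled in config"}

    report["contrasts"] = contrasts

    # --- weight-class profiles -------------------------------------------
    if n_weighted:
        profiles = wmod.profile_all_classes(
            filtered, n_null=config.weight_class_nulls, seed=rng_seed + 91,
            attempts_per_edge=config.attempts_per_edge,
        )
        report["weight_classes"] = profiles.to_dict(orient="records")
    else:
        report["weight_classes"] = {"skipped": "no weighted edges"}

    # side tables callers may want to export
    report["_tables"] = {
        "node_metrics": node_table,
        "hub_scores": hubs_table,
        "edge_records": records,
        "degree_ratio": ratio_table,
    }
    return report


def report_to_json(report: dict) -> dict:
    """Report without the DataFrame side tables, with JSON-clean scalars."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return _json_safe(clean)


def validate_report(report: dict) -> None:
    """Minimal schema check before writing: required blocks present."""
    required = (
        "schema_version", "config", "network", "global_metrics", "partition",
        "hubs", "rich_club", "edge_classes", "contrasts", "weight_classes",
    )
    missing = [k for k in required if k not in report]
    if missing:
        raise ValueError(f"report is missing blocks: {missing}")


def export_tables(report: dict, out_dir) -> list[str]:
    """Write the side tables as TSVs; returns the filenames written."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in report.get("_tables", {}).items():
        if isinstance(frame, pd.DataFrame):
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=True, index_label="node")
            written.append(path.name)
    return written
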