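#!/usr/bin/env python
"""Edge classes and edge-level statistics.

Classifies every projection (rich club / feeder / local, intra- vs
intermodular, reciprocity), measures projection distances, wiring cost and
edge module diversity, and runs the class contrasts (strength, cost, EMD,
participation).  Writes edges_annotated.tsv and edge_stats.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_dataset, parser, write_json  # noqa: E402

import numpy as np  # noqa: E402

from ratconn.community import (hierarchical_partition, module_diversity,  # noqa: E402
                               participation_coefficient)
from ratconn.edges import (class_shares, classify_edges, edge_distances,  # noqa: E402
                           edge_module_diversity, wiring_cost)
from ratconn.io import binary_adjacency  # noqa: E402
from ratconn.metrics import node_metrics_table  # noqa: E402
from ratconn.richclub import hub_scores  # noqa: E402
from ratconn.stats import permutation_test  # noqa: E402


def main() -> None:
    args = parser(__doc__).parse_args()
    connectome, _ = load_dataset(args.seed)
    adj = binary_adjacency(connectome)

    top, _ = hierarchical_partition(adj, seed=args.seed)
    participation = participation_coefficient(adj, top)
    diversity = module_diversity(adj, top)
    table = node_metrics_table(adj, participation=participation)
    hubs = np.flatnonzero(hub_scores(table)["is_hub"].to_numpy())

    records = classify_edges(connectome, hubs, top)
    records = edge_module_diversity(records, diversity)
    records, dist_summary = edge_distances(connectome, records)
    records, cost_contrasts = wiring_cost(records, n_perm=args.perms,
                                          seed=args.seed)
    shares = class_shares(records)

    print(shares.to_string(index=False))
    corr = dist_summary["correlation"]
    print(f"distance–strength r = {corr['r']:.3f} (p = {corr['p']:.2g})")
    for name, res in cost_contrasts.items():
        print(f"cost {name}: ratio {res.ratio:.2f} (p = {res.p:.4f})")

    weighted = records.dropna(subset=["strength"])
    intra = weighted.loc[weighted["modular"] == "intra", "strength"]
    inter = weighted.loc[weighted["modular"] == "inter", "strength"]
    strength_mod = permutation_test(intra, inter, n_perm=args.perms,
                                    seed=args.seed + 1)
    print(f"strength intra {strength_mod.mean_a:.2f} vs inter "
          f"{strength_mod.mean_b:.2f} (p = {strength_mod.p:.4f})")

    RESULTS.mkdir(parents=True, exist_ok=True)
    records.to_csv(RESULTS / "edges_annotated.tsv", sep="\t", index=False)
    path = write_json("edge_stats.json", {
        "shares": shares.to_dict(orient="records"),
        "distances": dist_summary,
        "wiring_cost": {k: {"ratio": v.ratio, "p": v.p}
                        for k, v in cost_contrasts.items()},
        "strength_intra_vs_inter": {
            "mean_intra": strength_mod.mean_a,
            "mean_inter": strength_mod.mean_b, "p": strength_mod.p,
        },
        "n_perm": args.perms,
    })
    print(f"wrote {path} and edges_annotated.tsv")


if __name__ == "__main__":
    main()
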