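#!/usr/bin/env python
"""Global descriptives: clustering, path length, small-world, sinks/sources.

Normalizes clustering and path length against degree-preserving rewired
nulls (γ, λ, small-world index), summarizes the out/in-degree balance of
every region, and writes results/descriptives.json plus the per-node
metric table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_dataset, parser, write_json  # noqa: E402

import numpy as np  # noqa: E402

from ratconn.edges import degree_ratio_analysis, hl_ratio_analysis  # noqa: E402
from ratconn.io import binary_adjacency  # noqa: E402
from ratconn.metrics import (clustering_coefficient, global_metrics,  # noqa: E402
                             node_metrics_table, path_lengths, small_world)
from ratconn.nulls import build_ensemble  # noqa: E402


def main() -> None:
    args = parser(__doc__).parse_args()
    connectome, _ = load_dataset(args.seed)
    adj = binary_adjacency(connectome)
    gm = global_metrics(adj)
    ens = build_ensemble(
        adj,
        {"C": lambda a: clustering_coefficient(a)[1],
         "L": lambda a: path_lengths(a).L},
        n_null=args.nulls, seed=args.seed,
    )
    gamma, lam, sw = small_world(
        gm.C, gm.L, ens.metric_distributions["C"], ens.metric_distributions["L"]
    )
    table = node_metrics_table(adj)
    ratios, ratio_summary = degree_ratio_analysis(table)
    _, hl_summary = hl_ratio_analysis(connectome, table)

    print(f"density {100 * gm.density:.1f} %  C {gm.C:.3f}  L {gm.L:.3f}  "
          f"diameter {gm.diameter:.0f}")
    print(f"gamma {gamma:.3f}  lambda {lam:.3f}  small-world {sw:.3f} "
          f"({args.nulls} nulls)")
    print(f"sinks {ratio_summary['n_sinks']}  sources "
          f"{ratio_summary['n_sources']}  balanced fraction "
          f"{ratio_summary['balanced_fraction']:.2f}")

    table.insert(0, "abbr", connectome.regions.abbreviations)
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "node_metrics.tsv", sep="\t", index=False)
    path = write_json("descriptives.json", {
        "density": gm.density, "C": gm.C, "L": gm.L,
        "efficiency": gm.efficiency, "diameter": gm.diameter,
        "gamma": gamma, "lambda": lam, "small_world": sw,
        "n_null": args.nulls,
        "degree_ratio": ratio_summary, "hl_ratio": hl_summary,
    })
    print(f"wrote {path} and node_metrics.tsv")


if __name__ == "__main__":
    main()
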