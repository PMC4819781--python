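"""Edge classification, distances, cost, EMD, ratio analyses, perturbation."""

import numpy as np
import pandas as pd
import pytest

from ratconn.community import ModulePartition, newman_partition, module_diversity
from ratconn.edges import (
    EDGE_CLASSES, class_shares, classify_edges, degree_ratio_analysis,
    edge_distances, edge_module_diversity, edge_perturbation, hl_ratio,
    hl_ratio_analysis, perturbation_class_summary, wiring_cost,
)
from ratconn.io import UNKNOWN, binary_adjacency, from_arrays
from ratconn.metrics import node_metrics_table
from .conftest import connectome_from_adj, make_adj
from .oracles import communicability_by_series


def trivial_partition(n: int, labels=None) -> ModulePartition:
    return ModulePartition(
        np.zeros(n, dtype=int) if labels is None else np.asarray(labels), Q=0.0
    )


class TestClassifyEdges:
    def test_definition_table(self):
        # 0, 1 hubs; 2, 3 peripheral
        c = from_arrays([0, 0, 2, 2], [1, 2, 1, 3], n_regions=4)
        records = classify_edges(c, np.array([0, 1]), trivial_partition(4))
        assert list(records["clazz"]) == [
            "rich_club", "feeder_out", "feeder_in", "local"
        ]

    def test_mutual_pair_bidirectional(self):
        c = from_arrays([0, 1], [1, 0], n_regions=2)
        records = classify_edges(c, np.array([]), trivial_partition(2))
        assert records["bidirectional"].all()

    def test_bidirectional_symmetric(self, default_synth):
        c, truth = default_synth
        part = trivial_partition(c.n_regions, truth.top_modules)
        records = classify_edges(c, truth.hubs, part)
        flags = {(r.source, r.target): r.bidirectional
                 for r in records.itertuples()}
        for (s, t), flag in flags.items():
            if (t, s) in flags:
                assert flags[(t, s)] == flag
            else:
                assert not flag

    def test_shares_sum_to_one_and_match_relabeling(self, default_synth):
        c, truth = default_synth
        part = trivial_partition(c.n_regions, truth.top_modules)
        records = classify_edges(c, truth.hubs, part)
        shares = class_shares(records)
        assert shares["share"].sum() == pytest.approx(1.0)
        hub_set = set(truth.hubs.tolist())
        for s, t, _ in c.edges:  # independent per-edge relabeling
            expected = ("rich_club" if s in hub_set and t in hub_set
                        else "feeder_out" if s in hub_set
                        else "feeder_in" if t in hub_set else "local")
            row = records[(records.source == s) & (records.target == t)]
            assert row["clazz"].iloc[0] == expected

    def test_planted_classes_match(self, default_synth):
        c, truth = default_synth
        part = trivial_partition(c.n_regions, truth.top_modules)
        records = classify_edges(c, truth.hubs, part)
        assert list(records["clazz"]) == list(truth.edge_classes)


class TestDistances:
    def test_three_four_five(self):
        coords = np.array([[0.0, 0, 0], [3.0, 4, 0], [1.0, 1, 1]])
        c = from_arrays([0, 1], [1, 2], [5, 5], coords=coords, n_regions=3)
        records = classify_edges(c, np.array([]), trivial_partition(3))
        records, _ = edge_distances(c, records)
        assert records.loc[0, "distance"] == pytest.approx(5.0)

    def test_identical_coordinates_flagged(self):
        coords = np.zeros((3, 3))
        c = from_arrays([0, 1], [1, 2], [5, 3], coords=coords, n_regions=3)
        records = classify_edges(c, np.array([]), trivial_partition(3))
        _, summary = edge_distances(c, records)
        assert summary["correlation"] is None

    def test_no_coordinates_rejected(self, tiny_connectome):
        records = classify_edges(tiny_connectome, np.array([]),
                                 trivial_partition(3))
        with pytest.raises(ValueError, match="coordinates"):
            edge_distances(tiny_connectome, records)

    def test_planted_negative_correlation(self, default_synth):
        c, _ = default_synth
        records = classify_edges(c, np.array([]),
                                 trivial_partition(c.n_regions))
        _, summary = edge_distances(c, records)
        corr = summary["correlation"]
        assert corr["r"] < 0 and corr["p"] < 0.01


class TestWiringCost:
    def test_cost_is_product(self):
        coords = np.array([[0.0, 0, 0], [3.0, 4, 0]])
        c = from_arrays([0], [1], [7], coords=coords, n_regions=2)
        records = classify_edges(c, np.array([]), trivial_partition(2))
        records, _ = edge_distances(c, records)
        records, _ = wiring_cost(records, n_perm=10, seed=0)
        assert records.loc[0, "cost"] == pytest.approx(35.0)

    def test_equal_strengths_cost_orders_by_distance(self, default_synth):
        c, _ = default_synth
        records = classify_edges(c, np.array([]),
                                 trivial_partition(c.n_regions))
        records, _ = edge_distances(c, records)
        records["strength"] = 3.0
        records, _ = wiring_cost(records, n_perm=10, seed=0)
        assert np.array_equal(np.argsort(records["cost"].to_numpy()),
                              np.argsort(records["distance"].to_numpy()))


class TestEdgeModuleDiversity:
    def test_products(self):
        records = pd.DataFrame({"source": [0, 1], "target": [1, 2]})
        out = edge_module_diversity(records, np.array([1.0, 0.5, 0.5]))
        assert list(out["emd"]) == [0.5, 0.25]

    def test_class_means_match_brute_force(self, default_synth):
        c, truth = default_synth
        adj = binary_adjacency(c)
        part = newman_partition(adj)
        p = module_diversity(adj, part)
        records = classify_edges(c, truth.hubs, part)
        records = edge_module_diversity(records, p)
        for clazz in EDGE_CLASSES:
            sub = records[records["clazz"] == clazz]
            expected = np.mean([
                p[r.source] * p[r.target] for r in sub.itertuples()
            ])
            assert sub["emd"].mean() == pytest.approx(expected)


class TestDegreeRatios:
    def test_cycle_all_balanced(self, cycle5):
        table, summary = degree_ratio_analysis(node_metrics_table(cycle5))
        assert (table["role"] == "balanced").all()
        assert summary["balanced_fraction"] == 1.0

    def test_source_label(self):
        adj = make_adj(5, [(0, 1), (0, 2), (0, 3), (4, 0)])
        table, _ = degree_ratio_analysis(node_metrics_table(adj))
        assert table.loc[0, "out_in_ratio"] == pytest.approx(3.0)
        assert table.loc[0, "role"] == "source"

    def test_planted_sources_and_sinks_recovered(self, default_synth):
        c, truth = default_synth
        table, summary = degree_ratio_analysis(
            node_metrics_table(binary_adjacency(c))
        )
        found_sources = set(np.flatnonzero(table["role"] == "source"))
        found_sinks = set(np.flatnonzero(table["role"] == "sink"))
        assert found_sources == set(truth.sources.tolist())
        assert found_sinks == set(truth.sinks.tolist())


class TestHLRatio:
    def test_mixed_strengths(self):
        c = from_arrays([0, 0, 0, 1], [1, 2, 3, 0], [5, 6, 7, 2], n_regions=4)
        hl = hl_ratio(c)
        assert hl[0] == pytest.approx(3.0)  # {5,6,7} high vs {2} low

    def test_boundary_strength_four_is_low(self):
        c = from_arrays([0, 1], [1, 2], [4, 4], n_regions=3)
        assert np.all(hl_ratio(c)[:2] == 0.0)

    def test_planted_degree_coupling(self, default_synth):
        c, _ = default_synth
        table = node_metrics_table(binary_adjacency(c))
        _, summary = hl_ratio_analysis(c, table)
        assert summary["hl_vs_degree"]["r"] > 0


@pytest.fixture(scope="module")
def small_scan():
    rng = np.random.default_rng(0)
    adj = (rng.random((12, 12)) < 0.45).astype(np.int8)
    np.fill_diagonal(adj, 0)
    strengths = rng.integers(1, 8, size=(12, 12))
    c = connectome_from_adj(adj, strengths)
    return c, edge_perturbation(c)


class TestPerturbation:

    def test_global_communicability_never_increases(self, small_scan):
        _, scan = small_scan
        assert (scan["dcomm_global_pct"] <= 1e-9).all()

    def test_path_length_never_decreases_when_connected(self, small_scan):
        _, scan = small_scan
        connected = scan[~scan["disconnects"]]
        assert (connected["dL_pct"] >= -1e-9).all()

    def test_two_node_closed_form(self):
        c = from_arrays([0, 1], [1, 0], n_regions=2)
        scan = edge_perturbation(c)
        # before: exp([[0,1],[1,0]])[0,1] = sinh(1); after removing 0→1 the
        # remaining matrix is nilpotent and exp(A)[0,1] = 0
        before = np.sinh(1.0)
        expected = 100.0 * (0.0 - before) / before
        row = scan[(scan.source == 0) & (scan.target == 1)].iloc[0]
        assert row["dcomm_local_pct"] == pytest.approx(expected)
        series = communicability_by_series(np.array([[0, 0], [1, 0]]))
        assert series[0, 1] == 0.0

    def test_class_summary_matches_groupby(self, small_scan):
        c, scan = small_scan
        records = classify_edges(c, np.array([0, 1, 2]),
                                 trivial_partition(c.n_regions))
        summary = perturbation_class_summary(scan, records)
        merged = scan.merge(records[["source", "target", "clazz"]],
                            on=["source", "target"])
        for clazz in merged["clazz"].unique():
            expected = merged.loc[merged["clazz"] == clazz, "dL_pct"].mean()
            got = summary[(summary["grouping"] == "clazz")
                          & (summary["group"] == clazz)]["dL_pct"].iloc[0]
            assert got == pytest.approx(expected)

    def test_rich_club_edges_hit_communicability_harder(self, default_synth):
        c, truth = default_synth
        scan = edge_perturbation(c)
        records = classify_edges(c, truth.hubs,
                                 trivial_partition(c.n_regions))
        merged = scan.merge(records[["source", "target", "clazz"]],
                            on=["source", "target"])
        rc = merged.loc[merged["clazz"] == "rich_club", "dcomm_global_pct"]
        local = merged.loc[merged["clazz"] == "local", "dcomm_global_pct"]
        assert rc.abs().mean() > local.abs().mean()
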