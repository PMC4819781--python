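"""Rich-club curve, null-normalized significance, hub scoring."""

import numpy as np
import pandas as pd
import pytest

from ratconn.io import binary_adjacency
from ratconn.nulls import build_ensemble
from ratconn.richclub import (
    hub_phi_metric, hub_scores, hub_set_rich_club, phi_vector,
    rich_club_curve, rich_club_significance,
)
from ratconn.synth import SyntheticParams, generate
from .conftest import make_adj
from .oracles import rich_club_by_counting


class TestRichClubCurve:
    def test_complete_digraph_all_one(self, complete4):
        curve = rich_club_curve(complete4)
        assert np.allclose(curve.phi, 1.0)

    def test_star_graph(self):
        # hub 0 ↔ 4 leaves, leaves unconnected
        edges = [(0, i) for i in range(1, 5)] + [(i, 0) for i in range(1, 5)]
        adj = make_adj(5, edges)
        curve = rich_club_curve(adj)
        # phi(0): all 5 nodes, 8 edges of 20 slots
        assert curve.phi[curve.k == 0][0] == pytest.approx(8 / 20)
        # above leaf degree only the hub remains → no entry (N_>k < 2)
        assert curve.k.max() < 8

    def test_matches_direct_counting(self, digraph_factory):
        rng = np.random.default_rng(0)
        for _ in range(100):
            adj = digraph_factory(25, rng.uniform(0.1, 0.5), rng)
            curve = rich_club_curve(adj)
            for k, phi in zip(curve.k, curve.phi):
                assert phi == pytest.approx(rich_club_by_counting(adj, int(k)))

    def test_n_gt_k_non_increasing(self, digraph_factory):
        rng = np.random.default_rng(1)
        adj = digraph_factory(30, 0.3, rng)
        curve = rich_club_curve(adj)
        assert np.all(np.diff(curve.n_gt_k) <= 0)


class TestSignificance:
    def test_self_ensemble_norm_is_one(self, digraph_factory):
        rng = np.random.default_rng(2)
        adj = digraph_factory(20, 0.3, rng)
        grid = rich_club_curve(adj).k
        phi = phi_vector(adj, grid)
        ens_like = build_ensemble(adj, {"phi": lambda a: phi_vector(a, grid)},
                                  n_null=5, seed=0, attempts_per_edge=0)
        curve = rich_club_significance(adj, ens_like)
        assert np.allclose(curve.phi_norm, 1.0, equal_nan=True)

    def test_planted_rich_club_detected(self):
        # dense hub core over sparse background
        rng = np.random.default_rng(3)
        n, n_hubs = 40, 8
        adj = (rng.random((n, n)) < 0.25).astype(np.int8)
        hub_block = (rng.random((n_hubs, n_hubs)) < 0.9).astype(np.int8)
        adj[:n_hubs, :n_hubs] = hub_block
        np.fill_diagonal(adj, 0)
        grid = rich_club_curve(adj).k
        ens = build_ensemble(adj, {"phi": lambda a: phi_vector(a, grid)},
                             n_null=300, seed=4)
        curve = rich_club_significance(adj, ens)
        upper = curve.k >= np.percentile(curve.k, 70)
        assert np.nanmax(curve.phi_norm[upper]) > 1.0
        assert np.nanmin(curve.p[upper]) < 0.01
        assert curve.significant_range(0.01) is not None

    def test_grid_mismatch_rejected(self, digraph_factory):
        rng = np.random.default_rng(5)
        adj = digraph_factory(15, 0.3, rng)
        bad = build_ensemble(adj, {"phi": lambda a: np.array([1.0, 2.0])},
                             n_null=3, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            rich_club_significance(adj, bad)


class TestHubScores:
    @staticmethod
    def metric_frame(values: dict) -> pd.DataFrame:
        return pd.DataFrame(values)

    def test_top_on_all_five_scores_five(self):
        n = 9
        frame = self.metric_frame({
            "k_in": [9] + [1] * (n - 1),
            "k_out": [9] + [1] * (n - 1),
            "B_i": [0.9] + [0.1] * (n - 1),
            "P_i": [0.8] + [0.2] * (n - 1),
            "L_i": [1.0] + [3.0] * (n - 1),
        })
        scores = hub_scores(frame)
        assert scores.loc[0, "score"] == 5 and scores.loc[0, "is_hub"]

    def test_bottom_on_all_five_scores_zero(self):
        n = 9
        frame = self.metric_frame({
            "k_in": [1] + list(range(10, 10 + n - 1)),
            "k_out": [1] + list(range(10, 10 + n - 1)),
            "B_i": [0.0] + [0.5] * (n - 1),
            "P_i": [0.0] + [0.5] * (n - 1),
            "L_i": [9.0] + [1.0] * (n - 1),
        })
        scores = hub_scores(frame)
        assert scores.loc[0, "score"] == 0 and not scores.loc[0, "is_hub"]

    def test_boundary_ties_all_included(self):
        frame = self.metric_frame({
            "k_in": [5, 5, 5, 5, 1, 1],   # tie at the 33 % boundary
            "k_out": [1, 2, 3, 4, 5, 6],
            "B_i": [0.1] * 6,
            "P_i": [0.1] * 6,
            "L_i": [2.0] * 6,
        })
        scores = hub_scores(frame, top_fraction=0.33)
        assert scores["top_k_in"].sum() == 4

    def test_nan_ranks_last(self):
        frame = self.metric_frame({
            "k_in": [3, 2, 1, 0, 0, 0],
            "k_out": [3, 2, 1, 0, 0, 0],
            "B_i": [0.3, 0.2, 0.1, 0.0, 0.0, 0.0],
            "P_i": [0.3, 0.2, 0.1, 0.0, 0.0, 0.0],
            "L_i": [np.nan, 1.0, 2.0, 3.0, 4.0, 5.0],
        })
        scores = hub_scores(frame)
        assert not scores.loc[0, "top_L_i"]

    def test_planted_hubs_recovered(self, default_synth):
        from ratconn.community import (hierarchical_partition,
                                       participation_coefficient)
        from ratconn.metrics import node_metrics_table

        c, truth = default_synth
        adj = binary_adjacency(c)
        top, _ = hierarchical_partition(adj, seed=1)
        p = participation_coefficient(adj, top)
        table = node_metrics_table(adj, participation=p)
        found = set(np.flatnonzero(hub_scores(table)["is_hub"].to_numpy()))
        planted = set(truth.hubs.tolist())
        jaccard = len(found & planted) / len(found | planted)
        assert jaccard >= 0.8


class TestHubSetRichClub:
    def test_whole_complete_digraph(self, complete4):
        ens = build_ensemble(
            complete4, {"phi_H": hub_phi_metric(np.arange(4))},
            n_null=20, seed=0,
        )
        phi_h, null_mean, p = hub_set_rich_club(complete4, np.arange(4), ens)
        assert phi_h == 1.0 and null_mean == 1.0
        assert p == pytest.approx(1.0)  # nulls identical to observation

    def test_density_arithmetic_14_nodes(self):
        # 14 hubs, 120 internal directed edges → phi_H = 120/182
        rng = np.random.default_rng(9)
        n = 30
        adj = np.zeros((n, n), dtype=np.int8)
        slots = [(s, t) for s in range(14) for t in range(14) if s != t]
        chosen = rng.choice(len(slots), 120, replace=False)
        for i in chosen:
            adj[slots[i]] = 1
        adj[14:, 0] = 1  # keep the rest attached
        ens = build_ensemble(adj, {"phi_H": hub_phi_metric(np.arange(14))},
                             n_null=5, seed=1)
        phi_h, _, _ = hub_set_rich_club(adj, np.arange(14), ens)
        assert phi_h == pytest.approx(120 / 182)

    def test_planted_hub_set_significant(self, default_synth):
        c, truth = default_synth
        adj = binary_adjacency(c)
        ens = build_ensemble(adj, {"phi_H": hub_phi_metric(truth.hubs)},
                             n_null=150, seed=2)
        _, _, p = hub_set_rich_club(adj, truth.hubs, ens)
        assert p < 0.05

    def test_small_hub_set_rejected(self, complete4):
        ens = build_ensemble(complete4, {"phi_H": lambda a: 1.0},
                             n_null=3, seed=0)
        with pytest.raises(ValueError):
            hub_set_rich_club(complete4, np.array([0]), ens)
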