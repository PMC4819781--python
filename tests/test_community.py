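"""Modularity partitioning, hierarchy, participation, module diversity."""

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from ratconn.community import (
    ModulePartition, hierarchical_partition, modularity, module_diversity,
    newman_partition, participation_coefficient, submodule_counts, symmetrize,
)
from .conftest import make_adj
from .oracles import best_partition_exhaustive, modularity_undirected


def two_triangles_with_bridge() -> np.ndarray:
    # bidirectional triangles {0,1,2} and {3,4,5}, one bidirectional bridge 2↔3
    pairs = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    edges = [(s, t) for s, t in pairs] + [(t, s) for s, t in pairs]
    return make_adj(6, edges)


def planted_blocks(n: int, k: int, p_in: float, p_out: float,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), n // k)
    same = labels[:, None] == labels[None, :]
    p = np.where(same, p_in, p_out)
    adj = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj, labels


class TestNewmanPartition:
    def test_two_triangles_recovered(self):
        adj = two_triangles_with_bridge()
        part = newman_partition(adj)
        assert part.n_modules == 2
        assert len(set(part.assignment[:3])) == 1
        assert len(set(part.assignment[3:])) == 1
        # found split attains the exhaustive-search maximum
        best_q, _ = best_partition_exhaustive(symmetrize(adj))
        assert part.Q == pytest.approx(best_q, abs=1e-9)

    def test_complete_digraph_single_module(self, complete4):
        part = newman_partition(complete4)
        assert part.n_modules == 1
        # any split of a complete graph has non-positive Q
        assert modularity(complete4, np.array([0, 0, 1, 1])) <= 0

    def test_planted_three_blocks(self):
        adj, labels = planted_blocks(60, 3, p_in=0.6, p_out=0.05, seed=0)
        part = newman_partition(adj)
        assert normalized_mutual_info_score(labels, part.assignment) >= 0.9

    def test_q_not_below_trivial_partition(self, digraph_factory):
        rng = np.random.default_rng(1)
        for _ in range(10):
            adj = digraph_factory(20, rng.uniform(0.1, 0.4), rng)
            assert newman_partition(adj).Q >= -1e-12

    def test_q_matches_double_loop_oracle(self, digraph_factory):
        rng = np.random.default_rng(2)
        adj = digraph_factory(15, 0.3, rng)
        part = newman_partition(adj)
        expected = modularity_undirected(symmetrize(adj), part.assignment)
        assert part.Q == pytest.approx(expected, abs=1e-12)

    def test_igraph_cross_check(self):
        # independent implementation of the same spectral method
        import igraph as ig

        adj, _ = planted_blocks(40, 2, p_in=0.5, p_out=0.05, seed=3)
        part = newman_partition(adj)
        g = ig.Graph.Adjacency(symmetrize(adj).tolist(), mode="undirected")
        theirs = g.community_leading_eigenvector(clusters=2)
        ours_q = part.Q
        theirs_q = g.modularity(theirs.membership)
        assert ours_q >= theirs_q - 0.02


class TestHierarchy:
    def test_two_level_planted_recovery(self):
        # 3 top blocks of 20 holding 1/2/3 sub-blocks; clean contrasts
        rng = np.random.default_rng(5)
        n = 60
        top = np.repeat(np.arange(3), 20)
        sub = np.repeat(np.arange(6), [20, 10, 10, 7, 7, 6])
        p = np.full((n, n), 0.03)
        p[top[:, None] == top[None, :]] = 0.22
        p[sub[:, None] == sub[None, :]] = 0.85
        adj = (rng.random((n, n)) < p).astype(np.int8)
        np.fill_diagonal(adj, 0)
        top_part, level2 = hierarchical_partition(adj, seed=0)
        assert top_part.n_modules == 3
        assert sorted(submodule_counts(top_part, level2)) == [1, 2, 3]
        assert normalized_mutual_info_score(sub, level2.assignment) >= 0.9

    def test_no_substructure_single_submodules(self):
        rng = np.random.default_rng(6)
        adj, _ = planted_blocks(40, 2, p_in=0.55, p_out=0.05, seed=6)
        top_part, level2 = hierarchical_partition(adj, seed=1)
        assert submodule_counts(top_part, level2) == [1] * top_part.n_modules

    def test_idempotent_on_recovered_submodule(self):
        adj, labels = planted_blocks(40, 2, p_in=0.55, p_out=0.05, seed=7)
        top_part, _ = hierarchical_partition(adj, seed=2)
        nodes = top_part.members(0)
        sub_adj = adj[np.ix_(nodes, nodes)]
        _, level2 = hierarchical_partition(sub_adj, seed=3)
        assert level2.n_modules == 1 or level2.parent is not None


class TestParticipation:
    def test_all_edges_within_module_zero(self):
        adj = make_adj(4, [(0, 1), (1, 0), (2, 3), (3, 2)])
        part = ModulePartition(np.array([0, 0, 1, 1]), Q=0.0)
        p = participation_coefficient(adj, part)
        assert np.allclose(p, 0.0)

    def test_even_split_across_four_modules(self):
        # node 0 sends one edge into each of four modules
        adj = make_adj(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        part = ModulePartition(np.array([0, 0, 1, 2, 3]), Q=0.0)
        p = participation_coefficient(adj, part)
        # endpoints: 1 in own module (node 1), 1 in each of three others
        assert p[0] == pytest.approx(1 - 4 * (1 / 4) ** 2)

    def test_bounded_by_module_count(self, default_synth):
        from ratconn.io import binary_adjacency

        adj = binary_adjacency(default_synth[0])
        part = newman_partition(adj)
        p = participation_coefficient(adj, part)
        m = part.n_modules
        valid = ~np.isnan(p)
        assert np.all(p[valid] >= 0) and np.all(p[valid] <= 1 - 1 / m + 1e-12)

    def test_isolated_node_flagged(self):
        adj = make_adj(3, [(0, 1)])
        part = ModulePartition(np.array([0, 0, 1]), Q=0.0)
        assert np.isnan(participation_coefficient(adj, part)[2])


class TestModuleDiversity:
    def test_neighbour_in_every_module(self):
        adj = make_adj(4, [(0, 1), (0, 2), (0, 3)])
        part = ModulePartition(np.array([0, 0, 1, 2]), Q=0.0)
        assert module_diversity(adj, part)[0] == pytest.approx(1.0)

    def test_own_module_only(self):
        adj = make_adj(6, [(0, 1), (1, 0)])
        part = ModulePartition(np.array([0, 0, 1, 1, 2, 2]), Q=0.0)
        p = module_diversity(adj, part)
        assert p[0] == pytest.approx(1 / 3)

    def test_single_module_all_ones(self, cycle5):
        part = ModulePartition(np.zeros(5, dtype=int), Q=0.0)
        assert np.allclose(module_diversity(cycle5, part), 1.0)
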