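"""Shared fixtures: canonical small digraphs, random-graph factories, and a
session-scoped default synthetic connectome."""

from __future__ import annotations

import numpy as np
import pytest

from ratconn.io import Connectome, RegionTable, from_arrays
from ratconn.synth import generate


def make_adj(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.int8)
    for s, t in edges:
        adj[s, t] = 1
    return adj


@pytest.fixture
def cycle5() -> np.ndarray:
    """Directed 5-cycle 0→1→2→3→4→0."""
    return make_adj(5, [(i, (i + 1) % 5) for i in range(5)])


@pytest.fixture
def complete4() -> np.ndarray:
    """Complete digraph on 4 nodes (all 12 ordered pairs)."""
    adj = np.ones((4, 4), dtype=np.int8)
    np.fill_diagonal(adj, 0)
    return adj


@pytest.fixture
def path3() -> np.ndarray:
    """Directed path a→b→c."""
    return make_adj(3, [(0, 1), (1, 2)])


def random_digraph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    adj = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


@pytest.fixture
def digraph_factory():
    return random_digraph


@pytest.fixture(scope="session")
def default_synth():
    """Default-parameter synthetic connectome with ground truth (seed 0)."""
    return generate(seed=0)


@pytest.fixture
def tiny_connectome() -> Connectome:
    """3 regions, edges A→B (5) and B→A (2)."""
    regions = RegionTable(("A", "B", "C"), ("a", "b", "c"))
    return Connectome(regions, ((0, 1, 5), (1, 0, 2)))


def connectome_from_adj(adj: np.ndarray, strengths: np.ndarray | None = None,
                        coords: np.ndarray | None = None) -> Connectome:
    srcs, tgts = np.nonzero(adj)
    strength = None if strengths is None else strengths[srcs, tgts]
    return from_arrays(srcs, tgts, strength, coords=coords,
                       n_regions=adj.shape[0])
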