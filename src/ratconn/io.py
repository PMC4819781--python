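"""Connectome containers and edge-list / region-table I/O.

A connectome is a directed graph over named brain regions whose edges carry an
ordinal tract-tracing strength class (1 = very weak ... 7 = very strong) or an
explicit UNKNOWN marker when a projection was reported without a strength.

The in-memory convention is always source→target: edge ``(s, t)`` means a
projection from region ``s`` to region ``t`` and appears as entry ``(s, t)``
of the adjacency matrix.  Collation databases that store "projection from j
to i" as matrix entry ``(i, j)`` are transposed once, at read time, via the
``convention`` flag — never downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for an edge whose projection strength was not reported.  Kept
#: distinct from 0 so that "absent edge" and "edge of unknown weight" never
#: collapse: unknown-weight edges participate in every binary analysis.
UNKNOWN: int = -1

STRENGTH_MIN, STRENGTH_MAX = 1, 7


class ConnectomeError(ValueError):
    """Malformed connectome input (duplicate edge, bad strength, unknown region)."""


class EmptyGraphError(ConnectomeError):
    """Raised when filtering removes every region."""


@dataclasses.dataclass(frozen=True)
class RegionTable:
    """Node table: contiguous integer ids, unique abbreviations, optional 3-D
    centre-of-mass coordinates (present for all regions or for none)."""

    abbreviations: tuple[str, ...]
    names: tuple[str, ...]
    coords: np.ndarray | None = None  # (n, 3) float array, or None

    def __post_init__(self) -> None:
        if len(self.abbreviations) != len(self.names):
            raise ConnectomeError("abbreviations and names differ in length")
        if len(set(self.abbreviations)) != len(self.abbreviations):
            raise ConnectomeError("region abbreviations must be unique")
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (len(self.abbreviations), 3):
                raise ConnectomeError(
                    f"coords must be ({len(self.abbreviations)}, 3), got {coords.shape}"
                )
            object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.abbreviations)

    def index_of(self, abbr: str) -> int:
        try:
            return self.abbreviations.index(abbr)
        except ValueError:
            raise ConnectomeError(f"unknown region abbreviation: {abbr!r}") from None


@dataclasses.dataclass(frozen=True)
class Connectome:
    """Directed weighted connectome.

    ``edges`` is a tuple of ``(source, target, strength)`` with strengths in
    1..7 or :data:`UNKNOWN`; no self-loops, no duplicate (source, target)
    pairs, endpoints within the region table.
    """

    regions: RegionTable
    edges: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.regions)
        seen: set[tuple[int, int]] = set()
        for s, t, w in self.edges:
            if s == t:
                raise ConnectomeError(f"self-loop on region {s}")
            if not (0 <= s < n and 0 <= t < n):
                raise ConnectomeError(f"edge ({s}, {t}) outside region table")
            if (s, t) in seen:
                raise ConnectomeError(
                    f"duplicate edge {self.regions.abbreviations[s]}→"
                    f"{self.regions.abbreviations[t]}"
                )
            seen.add((s, t))
            if w != UNKNOWN and not (STRENGTH_MIN <= w <= STRENGTH_MAX):
                raise ConnectomeError(f"strength {w} outside 1–7 on edge ({s}, {t})")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        n = self.n_regions
        return self.n_edges / (n * (n - 1)) if n > 1 else float("nan")

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 3) int array of (source, target, strength)."""
        if not self.edges:
            return np.empty((0, 3), dtype=np.int64)
        return np.asarray(self.edges, dtype=np.int64)

    def has_edge(self, s: int, t: int) -> bool:
        return any(e[0] == s and e[1] == t for e in self.edges)

    def reverse(self) -> "Connectome":
        """Connectome with every edge direction flipped (strengths kept)."""
        return Connectome(self.regions, tuple((t, s, w) for s, t, w in self.edges))


def binary_adjacency(c: Connectome) -> np.ndarray:
    """Binary adjacency: entry (s, t) = 1 iff edge s→t exists.

    Unknown-strength edges are included — the binary graph sees every
    reported projection.  Diagonal is zero by construction.
    """
    n = c.n_regions
    adj = np.zeros((n, n), dtype=np.int8)
    if c.edges:
        e = c.edge_array()
        adj[e[:, 0], e[:, 1]] = 1
    return adj


def weight_matrix(c: Connectome) -> tuple[np.ndarray, int, float]:
    """Strength matrix plus weighted-edge bookkeeping.

    Returns ``(W, n_weighted, weighted_fraction)`` where ``W`` holds 1–7 for
    known strengths, :data:`UNKNOWN` where an edge exists with unreported
    strength, and 0 where there is no edge.
    """
    n = c.n_regions
    w = np.zeros((n, n), dtype=np.int64)
    n_weighted = 0
    for s, t, strength in c.edges:
        w[s, t] = strength
        if strength != UNKNOWN:
            n_weighted += 1
    frac = n_weighted / c.n_edges if c.n_edges else 0.0
    return w, n_weighted, frac


def filter_disconnected(c: Connectome) -> tuple[Connectome, list[int]]:
    """Drop regions with no connections or with connections only amongst
    themselves.

    Such regions form weak components separate from the bulk of the graph;
    the largest weak component is kept (ties broken toward the component
    containing the lowest region id) and everything else — isolated nodes
    and mutually isolated islands — is removed.  Idempotent.  Region ids are
    re-indexed contiguously; the removed original ids are returned.
    """
    n = c.n_regions
    # union-find over undirected edge support
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    touched = np.zeros(n, dtype=bool)
    for s, t, _ in c.edges:
        touched[s] = touched[t] = True
        rs, rt = find(s), find(t)
        if rs != rt:
            parent[max(rs, rt)] = min(rs, rt)

    components: dict[int, list[int]] = {}
    for i in range(n):
        if touched[i]:
            components.setdefault(find(i), []).append(i)
    if not components:
        raise EmptyGraphError("every region would be removed (no edges at all)")

    keep = sorted(max(components.values(), key=lambda m: (len(m), -min(m))))
    removed = sorted(set(range(n)) - set(keep))
    if not removed:
        return c, []

    old_to_new = {old: new for new, old in enumerate(keep)}
    regions = RegionTable(
        abbreviations=tuple(c.regions.abbreviations[i] for i in keep),
        names=tuple(c.regions.names[i] for i in keep),
        coords=None if c.regions.coords is None else c.regions.coords[keep],
    )
    edges = tuple(
        (old_to_new[s], old_to_new[t], w)
        for s, t, w in c.edges
        if s in old_to_new and t in old_to_new
    )
    return Connectome(regions, edges), removed


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_region_table(path: str | Path) -> RegionTable:
    """Read a region table TSV: ``abbr<TAB>name[<TAB>x<TAB>y<TAB>z]``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] not in (2, 5):
        raise ConnectomeError(
            f"region table must have 2 or 5 columns, got {df.shape[1]}"
        )
    coords = None
    if df.shape[1] == 5:
        coords = df.iloc[:, 2:5].astype(float).to_numpy()
    return RegionTable(
        abbreviations=tuple(df.iloc[:, 0].str.strip()),
        names=tuple(df.iloc[:, 1].str.strip()),
        coords=coords,
    )


def _parse_strength(raw: str | float) -> int:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNKNOWN
    text = str(raw).strip()
    if text in ("", "NA", "nan"):
        return UNKNOWN
    try:
        value = int(text)
    except ValueError:
        raise ConnectomeError(f"unparseable strength {raw!r}") from None
    if not (STRENGTH_MIN <= value <= STRENGTH_MAX):
        raise ConnectomeError(f"strength {value} outside 1–7")
    return value


def read_edge_list(
    path: str | Path,
    region_path: str | Path,
    convention: str = "source_target",
) -> Connectome:
    """Read an edge-list TSV (``source<TAB>target<TAB>strength``) against a
    region table.

    ``convention="source_target"`` takes the rows at face value.
    ``convention="bams_target_source"`` treats each row as a matrix entry
    (i, j) meaning a projection from j to i, i.e. stores row ``(i, j, w)``
    as edge j→i, converting to the internal source→target orientation.
    """
    if convention not in ("source_target", "bams_target_source"):
        raise ConnectomeError(f"unknown convention {convention!r}")
    regions = read_region_table(region_path)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        names=["a", "b", "strength"], keep_default_na=False,
    )
    edges = []
    for _, row in df.iterrows():
        i = regions.index_of(str(row["a"]).strip())
        j = regions.index_of(str(row["b"]).strip())
        w = _parse_strength(row["strength"])
        if convention == "bams_target_source":
            i, j = j, i
        edges.append((i, j, w))
    return Connectome(regions, tuple(edges))


def write_connectome(c: Connectome, edge_path: str | Path, region_path: str | Path) -> None:
    """Write edges.tsv / regions.tsv in the formats :func:`read_edge_list` reads."""
    abbr = c.regions.abbreviations
    with open(edge_path, "w") as fh:
        for s, t, w in c.edges:
            strength = "NA" if w == UNKNOWN else str(w)
            fh.write(f"{abbr[s]}\t{abbr[t]}\t{strength}\n")
    with open(region_path, "w") as fh:
        for i in range(c.n_regions):
            row = [abbr[i], c.regions.names[i]]
            if c.regions.coords is not None:
                row += [f"{v:.6g}" for v in c.regions.coords[i]]
            fh.write("\t".join(row) + "\n")


def to_networkx(c: Connectome):
    """Export as a ``networkx.DiGraph`` with ``strength`` edge attributes
    (None for unknown), e.g. for GraphML export."""
    import networkx as nx

    g = nx.DiGraph()
    for i, abbr in enumerate(c.regions.abbreviations):
        attrs = {"name": c.regions.names[i]}
        if c.regions.coords is not None:
            attrs.update(zip("xyz", map(float, c.regions.coords[i])))
        g.add_node(abbr, **attrs)
    for s, t, w in c.edges:
        g.add_edge(
            c.regions.abbreviations[s], c.regions.abbreviations[t],
            strength=int(w) if w != UNKNOWN else -1,
        )
    return g


def from_arrays(
    sources: Sequence[int] | np.ndarray,
    targets: Sequence[int] | np.ndarray,
    strengths: Sequence[int] | np.ndarray | None = None,
    abbreviations: Iterable[str] | None = None,
    coords: np.ndarray | None = None,
    n_regions: int | None = None,
) -> Connectome:
    """Build a Connectome from parallel arrays; convenience for generators
    and tests.  Default strength is UNKNOWN, default abbreviations R000.."""
    sources = np.asarray(sources, dtype=int)
    targets = np.asarray(targets, dtype=int)
    if strengths is None:
        strengths = np.full(len(sources), UNKNOWN, dtype=int)
    strengths = np.asarray(strengths, dtype=int)
    if n_regions is None:
        n_regions = int(max(sources.max(initial=-1), targets.max(initial=-1)) + 1)
    if abbreviations is None:
        abbreviations = tuple(f"R{i:03d}" for i in range(n_regions))
    abbreviations = tuple(abbreviations)
    regions = RegionTable(abbreviations, abbreviations, coords)
    edges = tuple(
        (int(s), int(t), int(w)) for s, t, w in zip(sources, targets, strengths)
    )
    return Connectome(regions, edges)
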