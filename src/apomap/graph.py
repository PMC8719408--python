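"""Areal adjacency graphs and the quadratic forms behind ICAR / RW1 priors.

The intrinsic conditional autoregressive (ICAR) prior on a per-area field
``u`` penalizes squared differences between neighbouring areas,

    p(u | tau) ∝ tau^(rank/2) * exp(-tau/2 * sum_{a~b} (u_a - u_b)^2),

where ``rank = n_areas - n_components`` is the rank of the graph Laplacian.
The random-walk-of-order-1 (RW1) prior on a per-period series is the same
penalty on the path graph of consecutive periods.  Everything downstream
(simulation, log-prior evaluation, conjugate precision updates) is expressed
through the two quadratic forms defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class SpatialGraph:
    """Symmetric areal adjacency structure.

    Parameters
    ----------
    n_areas:
        Number of areal units; areas are indexed ``0 .. n_areas-1``.
    edges:
        Deduplicated unordered neighbour pairs ``(a, b)`` with ``a < b``.
    area_ids:
        External string identifiers, position = internal index.
    """

    n_areas: int
    edges: tuple[tuple[int, int], ...]
    area_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.n_areas <= 0:
            raise ValueError("n_areas must be positive")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on area index {a}")
            if not (0 <= a < self.n_areas and 0 <= b < self.n_areas):
                raise ValueError(f"edge ({a},{b}) out of range")

    @cached_property
    def n_neighbors(self) -> np.ndarray:
        """Per-area neighbour count (Laplacian diagonal)."""
        deg = np.zeros(self.n_areas, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    @cached_property
    def components(self) -> list[frozenset[int]]:
        """Connected components; isolated areas are singletons."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return [frozenset(c) for c in nx.connected_components(g)]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def rank(self) -> int:
        """Rank of the graph Laplacian: n_areas - n_components."""
        return self.n_areas - self.n_components

    def component_labels(self) -> np.ndarray:
        """Integer component label per area (stable across calls)."""
        lab = np.empty(self.n_areas, dtype=int)
        for ci, comp in enumerate(sorted(self.components, key=min)):
            for a in comp:
                lab[a] = ci
        return lab

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two aligned integer arrays (may be empty)."""
        if not self.edges:
            z = np.zeros(0, dtype=int)
            return z, z
        e = np.asarray(self.edges, dtype=int)
        return e[:, 0], e[:, 1]

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian L = D - A."""
        L = np.zeros((self.n_areas, self.n_areas))
        for a, b in self.edges:
            L[a, b] -= 1.0
            L[b, a] -= 1.0
            L[a, a] += 1.0
            L[b, b] += 1.0
        return L

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return g

    def greedy_coloring(self) -> np.ndarray:
        """Proper vertex colouring; same-colour areas share no edge.

        Used by the sampler to update conditionally independent sites of a
        Markov random field in parallel.
        """
        col = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        return np.array([col[a] for a in range(self.n_areas)], dtype=int)


@dataclass(frozen=True)
class TemporalStructure:
    """Ordered annual (or other) periods over which RW1 effects live."""

    period_labels: tuple

    def __post_init__(self):
        if self.n_periods < 2:
            raise ValueError("need at least 2 periods for an RW1 prior")
        labs = list(self.period_labels)
        if any(labs[i] >= labs[i + 1] for i in range(len(labs) - 1)):
            raise ValueError("period labels must be strictly increasing")

    @property
    def n_periods(self) -> int:
        return len(self.period_labels)


def build_adjacency(edge_records, area_ids) -> SpatialGraph:
    """Build a deduplicated symmetric adjacency graph from an edge list.

    Areas in ``area_ids`` absent from ``edge_records`` become isolated
    (singleton components); they are never dropped.

    Parameters
    ----------
    edge_records:
        Iterable of ``(id_a, id_b)`` area-identifier pairs; order and
        duplication are irrelevant.
    area_ids:
        Ordered identifiers defining the internal 0-based indexing.

    Raises
    ------
    ValueError
        On an unknown area id or a self-loop pair.
    """
    ids = [str(a) for a in area_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("area_ids contains duplicates")
    index = {a: i for i, a in enumerate(ids)}
    edges: set[tuple[int, int]] = set()
    for rec in edge_records:
        a, b = str(rec[0]), str(rec[1])
        if a not in index:
            raise ValueError(f"unknown area id in edge list: {a!r}")
        if b not in index:
            raise ValueError(f"unknown area id in edge list: {b!r}")
        ia, ib = index[a], index[b]
        if ia == ib:
            raise ValueError(f"self-loop edge on area id {a!r}")
        edges.add((min(ia, ib), max(ia, ib)))
    return SpatialGraph(n_areas=len(ids), edges=tuple(sorted(edges)),
                        area_ids=tuple(ids))


def read_edge_list(path, area_ids=None) -> SpatialGraph:
    """Read a two-column (CSV or whitespace) edge list of area ids.

    If ``area_ids`` is None the registry is the sorted set of ids seen.
    """
    records = []
    seen: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            records.append((parts[0], parts[1]))
            seen.extend(parts[:2])
    if area_ids is None:
        area_ids = sorted(set(seen))
    return build_adjacency(records, area_ids)


def read_gal(path) -> SpatialGraph:
    """Read a GAL-dialect neighbour file.

    Format: a header line whose last field is the number of areas, then for
    each area a line ``id k`` followed by a line of its ``k`` neighbour ids.
    """
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh
                          if ln.strip() and not ln.startswith("#")]
    if not tokens_by_line:
        raise ValueError("empty GAL file")
    header = tokens_by_line[0]
    n = int(header[-1])
    flat = [t for line in tokens_by_line[1:] for t in line]
    pos = 0
    area_ids: list[str] = []
    neigh: dict[str, list[str]] = {}
    for _ in range(n):
        if pos + 1 >= len(flat) + 1:
            raise ValueError("truncated GAL file")
        aid, k = flat[pos], int(flat[pos + 1])
        pos += 2
        neigh[aid] = flat[pos:pos + k]
        if len(neigh[aid]) != k:
            raise ValueError(f"truncated neighbour list for area {aid!r}")
        pos += k
        area_ids.append(aid)
    records = [(a, b) for a, bs in neigh.items() for b in bs]
    return build_adjacency(records, area_ids)


def icar_quadform(field, graph: SpatialGraph) -> float:
    """Pairwise-difference quadratic form sum_{a~b} (field[a]-field[b])^2.

    Equals ``field @ L @ field`` for the graph Laplacian ``L``; the sum over
    edges avoids forming L.
    """
    f = np.asarray(field, dtype=float)
    if f.shape[0] != graph.n_areas:
        raise ValueError(
            f"field length {f.shape[0]} != n_areas {graph.n_areas}")
    ea, eb = graph.edge_arrays()
    d = f[ea] - f[eb]
    # supports trailing axes (e.g. per-outcome fields): sums edge axis only
    return np.sum(d * d, axis=0)


def rw1_quadform(series) -> float:
    """First-difference penalty sum_j (series[j+1]-series[j])^2."""
    s = np.asarray(series, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("series must have length >= 2")
    d = np.diff(s, axis=0)
    return np.sum(d * d, axis=0)


def path_graph(n: int) -> SpatialGraph:
    """Path graph 0-1-...-(n-1); RW1 is ICAR on this graph."""
    return SpatialGraph(n, tuple((i, i + 1) for i in range(n - 1)),
                        tuple(str(i) for i in range(n)))
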