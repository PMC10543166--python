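"""Structured populations for the evolutionary game simulator.

Three topologies are supported: a toroidal regular lattice with von Neumann
(4-neighbor) connectivity, a Barabasi-Albert scale-free graph, and an
implicit well-mixed population in which every player's crowd is the whole
remaining population.  Arbitrary simple graphs can be supplied as plain-text
edge lists.

Graphs are generated with :mod:`networkx` and stored in compressed sparse
row (CSR) form so that the dynamics kernel can run fully vectorized.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Network",
    "build_lattice",
    "build_scale_free",
    "build_well_mixed",
    "load_edge_list",
    "from_networkx",
]


@dataclass(frozen=True)
class Network:
    """An undirected simple graph over ``node_count`` players.

    A well-mixed population is represented implicitly (``adjacency`` is
    ``None``); every node's crowd set is the remaining ``Z - 1`` players and
    the mean degree is taken as ``Z - 1``.

    Attributes
    ----------
    node_count : int
        Population size ``Z``.
    kind : str
        One of ``lattice``, ``scale_free``, ``well_mixed``, ``custom``.
    adjacency : scipy.sparse.csr_array or None
        Symmetric 0/1 adjacency; ``None`` for well-mixed.
    """

    node_count: int
    kind: str
    adjacency: sp.csr_array | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.node_count < 1:
            raise ValueError(f"node_count must be positive, got {self.node_count}")
        if self.kind not in ("lattice", "scale_free", "well_mixed", "custom"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.kind == "well_mixed":
            if self.adjacency is not None:
                raise ValueError("well_mixed networks are implicit; adjacency must be None")
        elif self.adjacency is None:
            raise ValueError(f"kind {self.kind!r} requires an explicit adjacency")

    @property
    def well_mixed(self) -> bool:
        return self.kind == "well_mixed"

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degree k_i (crowd-set size |C_i|)."""
        if self.well_mixed:
            return np.full(self.node_count, self.node_count - 1, dtype=np.int64)
        return np.diff(self.adjacency.indptr).astype(np.int64)

    @property
    def edge_count(self) -> int:
        if self.well_mixed:
            return self.node_count * (self.node_count - 1) // 2
        return int(self.adjacency.nnz // 2)

    @property
    def mean_degree(self) -> float:
        """<k> = 2E / Z (Z - 1 for the implicit well-mixed case)."""
        return 2.0 * self.edge_count / self.node_count

    def neighbors(self, node: int) -> np.ndarray:
        if self.well_mixed:
            others = np.arange(self.node_count, dtype=np.int64)
            return others[others != node]
        a = self.adjacency
        return a.indices[a.indptr[node] : a.indptr[node + 1]].astype(np.int64)

    def to_networkx(self) -> nx.Graph:
        if self.well_mixed:
            return nx.complete_graph(self.node_count)
        g = nx.from_scipy_sparse_array(self.adjacency)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g

    def dump_edge_list(self, stream: io.TextIOBase) -> None:
        """Write the graph as ``i j`` lines, one undirected edge per line."""
        if self.well_mixed:
            raise ValueError("well_mixed networks are implicit and cannot be dumped")
        coo = sp.triu(self.adjacency, k=1).tocoo()
        for i, j in zip(coo.row, coo.col):
            stream.write(f"{i} {j}\n")


def from_networkx(graph: nx.Graph, kind: str = "custom") -> Network:
    """Wrap a networkx graph (self-loops stripped, labels relabeled 0..Z-1)."""
    graph = nx.convert_node_labels_to_integers(graph, ordering="sorted")
    graph.remove_edges_from(nx.selfloop_edges(graph))
    adj = sp.csr_array(nx.to_scipy_sparse_array(graph, format="csr", dtype=np.int8))
    return Network(node_count=graph.number_of_nodes(), kind=kind, adjacency=adj)


def build_lattice(rows: int, cols: int) -> Network:
    """Toroidal lattice with von Neumann connectivity: every degree is 4.

    Periodic boundaries are the only convention under which a regular
    lattice has degree exactly 4 at every node; dimensions below 3 would
    collapse wrap-around edges into duplicates, hence the precondition.
    """
    if rows < 3:
        raise ValueError(f"rows must be >= 3, got {rows}")
    if cols < 3:
        raise ValueError(f"cols must be >= 3, got {cols}")
    g = nx.grid_2d_graph(rows, cols, periodic=True)
    return from_networkx(g, kind="lattice")


def build_scale_free(n: int, m: int = 2, seed: int | None = None) -> Network:
    """Barabasi-Albert preferential-attachment graph.

    ``m`` edges attach each new node, so ``<k> = 2m(n-m)/n ~ 2m`` and every
    node has degree >= m.  The default ``m=2`` targets ``<k> ~ 4``.  Identical
    seeds produce identical graphs.
    """
    if m < 1:
        raise ValueError(f"attachment parameter m must be >= 1, got {m}")
    if n <= m:
        raise ValueError(f"need n > m, got n={n}, m={m}")
    # complete seed on m+1 nodes keeps every degree >= m (a star seed would
    # leave its leaves at degree 1)
    g = nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=nx.complete_graph(m + 1))
    return from_networkx(g, kind="scale_free")


def build_well_mixed(n: int) -> Network:
    """Implicit well-mixed population: every crowd set has size Z - 1."""
    if n < 2:
        raise ValueError(f"well-mixed population needs Z >= 2, got {n}")
    return Network(node_count=n, kind="well_mixed", adjacency=None)


def load_edge_list(source) -> Network:
    """Parse a whitespace-separated edge list into a custom Network.

    One ``i j`` pair per line; blank lines and ``#`` comments are skipped.
    Duplicate edges collapse; self-loops and non-integer tokens raise a
    ``ValueError`` naming the offending line.  Node ids are remapped to
    0-based contiguous integers in sorted order of the original labels.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    edges: set[tuple[int, int]] = set()
    nodes: set[int] = set()
    for lineno, line in enumerate(source, start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"line {lineno}: expected two tokens, got {len(tokens)}")
        try:
            u, v = int(tokens[0]), int(tokens[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer token in {line!r}") from exc
        if u == v:
            raise ValueError(f"line {lineno}: self-loop {u}--{v} not allowed")
        nodes.update((u, v))
        edges.add((min(u, v), max(u, v)))
    if not nodes:
        raise ValueError("empty edge list")
    relabel = {old: new for new, old in enumerate(sorted(nodes))}
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    g.add_edges_from((relabel[u], relabel[v]) for u, v in edges)
    return from_networkx(g, kind="custom")
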