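"""Interaction-network container, edge-list I/O, and adjacency normalizations.

The molecular interaction network is an undirected simple graph over opaque
node identifiers ("network objects": gene products, complexes, families).
Edge direction and mechanism annotations present in curated interaction
databases are parsed but discarded: none of the scoring methods downstream
uses them. Two normalized forms of the adjacency matrix are provided, a
column-stochastic one (random walk with restart) and a symmetric
degree-normalized one (network propagation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "InteractionNetwork",
    "NormalizedAdjacency",
    "NetworkParseError",
    "read_network",
    "write_network",
    "build_adjacency",
    "normalize_stochastic",
    "normalize_symmetric",
]


class NetworkParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class InteractionNetwork:
    """Undirected simple graph with a fixed, reproducible node order.

    Nodes are kept in first-appearance order so that matrix indices are
    stable across runs. Self-loops are dropped and duplicate (including
    reversed) edges collapse to a single undirected edge, mirroring the
    non-redundant merge of interaction sources.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = ()):
        self._graph = nx.Graph()
        self._order: list[str] = []
        for n in nodes:
            self.add_node(str(n))
        for u, v in edges:
            self.add_edge(str(u), str(v))

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        if node not in self._graph:
            self._graph.add_node(node)
            self._order.append(node)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:  # self-loops never enter the graph
            self.add_node(u)
            return
        self.add_node(u)
        self.add_node(v)
        self._graph.add_edge(u, v)

    # -- views ---------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        """Node identifiers in first-appearance order."""
        return list(self._order)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._graph.edges()}

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        """N(i): the set of nodes adjacent to ``node``."""
        return set(self._graph.neighbors(node))

    def degree(self, node: str) -> int:
        return self._graph.degree(node)

    def index(self) -> dict[str, int]:
        """Mapping node id -> row/column index in matrix representations."""
        return {n: i for i, n in enumerate(self._order)}

    def has_edge(self, u: str, v: str) -> bool:
        return self._graph.has_edge(u, v)

    def to_networkx(self) -> nx.Graph:
        return self._graph.copy()

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class NormalizedAdjacency:
    """A normalized adjacency matrix tagged with its normalization scheme.

    ``dangling`` flags columns of degree-0 nodes, which are all-zero under
    the column-stochastic scheme; the random walk redirects their mass to
    the restart vector.
    """

    matrix: sp.csr_matrix
    kind: str  # "column_stochastic" | "symmetric_degree"
    dangling: np.ndarray = field(repr=False)  # boolean per node


def read_network(path: str | Path, comment_prefix: str = "#",
                 fmt: str = "tsv") -> InteractionNetwork:
    """Read an undirected network from an edge-list file.

    Parameters
    ----------
    path
        Edge-list file. ``tsv`` format expects ``source<TAB>target`` with
        optional extra columns (mechanism, direction) that are ignored;
        ``sif`` expects ``source relation target``.
    comment_prefix
        Lines starting with this prefix are skipped.
    fmt
        ``"tsv"`` (default) or ``"sif"``.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {fmt!r}")
    net = InteractionNetwork()
    n_edges_seen = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            fields = line.split()
            if fmt == "tsv":
                if len(fields) < 2:
                    raise NetworkParseError(
                        f"{path}: line {lineno}: expected >=2 columns, "
                        f"got {len(fields)}")
                u, v = fields[0], fields[1]
            else:  # sif: source relation target [target ...]
                if len(fields) < 3:
                    raise NetworkParseError(
                        f"{path}: line {lineno}: SIF needs >=3 columns, "
                        f"got {len(fields)}")
                u, v = fields[0], fields[2]
            net.add_edge(u, v)
            n_edges_seen += 1
    if n_edges_seen == 0:
        raise NetworkParseError(f"{path}: no edges found")
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write the network as a two-column TSV edge list (isolated nodes as
    single-column lines are not representable; they are appended as
    self-referential comment lines for round-trip fidelity)."""
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        seen = set()
        for u in net.nodes:
            for v in sorted(net.neighbors(u)):
                key = frozenset((u, v))
                if key not in seen:
                    seen.add(key)
                    fh.write(f"{u}\t{v}\n")
        for u in net.nodes:
            if net.degree(u) == 0:
                fh.write(f"#isolated\t{u}\n")


def build_adjacency(net: InteractionNetwork) -> sp.csr_matrix:
    """Binary symmetric adjacency matrix in the network's node order."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return nx.adjacency_matrix(net.to_networkx(), nodelist=net.nodes,
                               dtype=float).tocsr()


def _degrees(adj: sp.spmatrix) -> np.ndarray:
    return np.asarray(adj.sum(axis=0)).ravel()


def normalize_stochastic(adj: sp.spmatrix) -> NormalizedAdjacency:
    """Column-stochastic normalization: entry(i,j) = e(i,j)/deg(j).

    Columns of degree-0 nodes stay all-zero and are flagged dangling.
    """
    adj = sp.csr_matrix(adj, dtype=float)
    deg = _degrees(adj)
    dangling = deg == 0
    inv = np.zeros_like(deg)
    inv[~dangling] = 1.0 / deg[~dangling]
    mat = (adj @ sp.diags(inv)).tocsr()
    return NormalizedAdjacency(matrix=mat, kind="column_stochastic",
                               dangling=dangling)


def normalize_symmetric(adj: sp.spmatrix) -> NormalizedAdjacency:
    """Symmetric degree normalization: entry(i,j) = e(i,j)/sqrt(deg(i)deg(j))."""
    adj = sp.csr_matrix(adj, dtype=float)
    deg = _degrees(adj)
    dangling = deg == 0
    inv_sqrt = np.zeros_like(deg)
    inv_sqrt[~dangling] = 1.0 / np.sqrt(deg[~dangling])
    d = sp.diags(inv_sqrt)
    mat = (d @ adj @ d).tocsr()
    return NormalizedAdjacency(matrix=mat, kind="symmetric_degree",
                               dangling=dangling)
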