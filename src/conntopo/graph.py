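"""Hydrogen-suppressed molecular graphs.

A molecule is modelled as a simple connected undirected graph: vertices are
heavy atoms, edges are bonds, hydrogens and bond orders are discarded.  The
central quantity is the *connection number* con(v) of a vertex — the number
of vertices at shortest-path distance exactly 2 — on which every descriptor
in :mod:`conntopo.indices` is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "GraphError",
    "ParseError",
    "MolecularGraph",
    "ConnectionProfile",
    "parse_edge_list",
    "distance_matrix",
    "connection_numbers",
    "from_smiles",
]


class GraphError(ValueError):
    """A structural requirement (simple, undirected, connected) is violated."""


class ParseError(GraphError):
    """An edge-list file could not be parsed into a valid molecular graph."""


@dataclass(frozen=True)
class MolecularGraph:
    """A validated simple connected undirected graph.

    Vertices are opaque string labels kept in first-appearance order; edges
    are stored as (u, v) pairs with u preceding v in vertex order, sorted,
    so that every edge iteration in the package is deterministic.
    """

    name: str
    vertices: Tuple[str, ...]
    edges: Tuple[Tuple[str, str], ...]
    adjacency: Mapping[str, frozenset] = field(repr=False)

    @staticmethod
    def from_edges(edges: Iterable[Tuple[str, str]], name: str = "",
                   vertices: Sequence[str] | None = None) -> "MolecularGraph":
        """Build and validate a graph from an iterable of vertex pairs.

        Vertex order is first-appearance order in ``edges`` unless an explicit
        ``vertices`` sequence is given (which may also add isolated-vertex
        labels, though those are rejected as disconnected).
        """
        order: Dict[str, int] = {}
        if vertices is not None:
            for v in vertices:
                order.setdefault(str(v), len(order))
        adj: Dict[str, set] = {v: set() for v in order}
        seen = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphError(f"self-loop at vertex {u!r}")
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                raise GraphError(f"duplicate edge {u!r}-{v!r}")
            seen.add(key)
            for w in (u, v):
                if w not in order:
                    order[w] = len(order)
                    adj[w] = set()
            adj[u].add(v)
            adj[v].add(u)
        if not order:
            raise GraphError("empty graph")
        verts = tuple(sorted(order, key=order.get))
        _check_connected(verts, adj)
        idx = {v: i for i, v in enumerate(verts)}
        sorted_edges = tuple(sorted(
            ((u, v) if idx[u] < idx[v] else (v, u) for (u, v) in seen),
            key=lambda e: (idx[e[0]], idx[e[1]]),
        ))
        frozen = {v: frozenset(s) for v, s in adj.items()}
        return MolecularGraph(name=name, vertices=verts, edges=sorted_edges,
                              adjacency=frozen)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: str) -> int:
        return len(self.adjacency[v])

    def degrees(self) -> Dict[str, int]:
        return {v: len(self.adjacency[v]) for v in self.vertices}

    def relabel(self, mapping: Mapping[str, str], name: str | None = None) -> "MolecularGraph":
        """Return an isomorphic copy under a vertex-relabeling permutation."""
        return MolecularGraph.from_edges(
            [(mapping[u], mapping[v]) for u, v in self.edges],
            name=self.name if name is None else name,
            vertices=[mapping[v] for v in self.vertices],
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def to_edge_list(self) -> str:
        """Serialize in the plain-text edge-list format of :func:`parse_edge_list`."""
        lines = [f"# {self.name}"] if self.name else []
        lines += [f"{u} {v}" for u, v in self.edges]
        return "\n".join(lines) + "\n"


def _check_connected(vertices: Sequence[str], adj: Mapping[str, Iterable[str]]) -> None:
    root = vertices[0]
    seen = {root}
    stack = [root]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != len(vertices):
        missing = [v for v in vertices if v not in seen]
        raise GraphError(
            "graph is disconnected: component containing "
            f"{root!r} does not reach {missing[:5]!r}"
        )


@dataclass(frozen=True)
class ConnectionProfile:
    """Per-vertex connection numbers con(v) of a molecular graph.

    con(v) counts vertices at shortest-path distance exactly 2 from v; it is
    bounded by 0 <= con(v) <= n - 1 - deg(v).
    """

    graph: MolecularGraph
    con: Mapping[str, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.con[v] for v in self.graph.vertices], dtype=int)

    def __getitem__(self, v: str) -> int:
        return self.con[v]


def parse_edge_list(text: str, name: str = "") -> MolecularGraph:
    """Parse a plain-text edge list into a validated :class:`MolecularGraph`.

    Each non-blank, non-comment line holds two whitespace-separated vertex
    labels; ``#`` starts a comment.  Errors name the offending line.
    """
    edges = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected two vertex labels, got {raw!r}")
        edges.append((parts[0], parts[1]))
    if not edges:
        raise ParseError("no edges found")
    try:
        return MolecularGraph.from_edges(edges, name=name)
    except ParseError:
        raise
    except GraphError as exc:
        raise ParseError(str(exc)) from exc


def distance_matrix(g: MolecularGraph) -> np.ndarray:
    """All-pairs shortest-path distances (edge counts) in vertex order.

    The result is symmetric with a zero diagonal; connectivity is guaranteed
    by construction so every entry is finite.
    """
    n = g.n_vertices
    idx = {v: i for i, v in enumerate(g.vertices)}
    dist = np.zeros((n, n), dtype=int)
    nxg = g.to_networkx()
    for v in g.vertices:
        lengths = nx.single_source_shortest_path_length(nxg, v)
        if len(lengths) != n:
            raise GraphError("graph is disconnected")  # pragma: no cover
        for u, d in lengths.items():
            dist[idx[v], idx[u]] = d
    return dist


def connection_numbers(g: MolecularGraph) -> ConnectionProfile:
    """Compute con(v) for every vertex with a 2-level breadth-first sweep.

    Avoids building the full distance matrix: the second neighborhood of v is
    the union of the neighbors' neighborhoods minus N(v) and v itself.
    """
    adj = g.adjacency
    con = {}
    for v in g.vertices:
        second: set = set()
        for u in adj[v]:
            second |= adj[u]
        second -= adj[v]
        second.discard(v)
        con[v] = len(second)
    return ConnectionProfile(graph=g, con=con)


def from_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Convert a SMILES string to its hydrogen-suppressed skeleton graph.

    Heavy atoms become vertices (labelled by 1-based atom index), bonds become
    edges, bond orders and charges are ignored.  Requires rdkit.
    """
    from rdkit import Chem  # optional dependency, imported lazily

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES {smiles!r}")
    edges = [(str(b.GetBeginAtomIdx() + 1), str(b.GetEndAtomIdx() + 1))
             for b in mol.GetBonds()]
    vertices = [str(i + 1) for i in range(mol.GetNumAtoms())]
    return MolecularGraph.from_edges(edges, name=name or smiles, vertices=vertices)
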