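"""Habitat networks for the metapopulation model.

Nodes are habitat patches and undirected, unweighted links are migration
paths.  Only connected graphs are allowed: random-walk migration has a
unique stationary density profile (proportional to node degree) only on a
connected graph.  A graph is *homogeneous* when all nodes share the same
degree and *heterogeneous* otherwise; this distinction decides whether the
three-species dynamics oscillate forever or relax to a stable focus.

Node labels in files and printed output are 1-based; internal storage is
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "GraphError",
    "complete_graph",
    "path_graph",
    "star_graph",
    "read_edge_list",
    "write_edge_list",
    "is_homogeneous",
]


class GraphError(ValueError):
    """Invalid habitat network (parse failure or violated invariant)."""


@dataclass(frozen=True)
class Graph:
    """Connected, undirected, unweighted habitat network.

    Parameters
    ----------
    n_nodes
        Number of habitat patches (>= 2).
    edges
        Unordered node-index pairs, 0-based, each stored as ``(i, j)``
        with ``i < j``.

    Attributes
    ----------
    degrees
        Per-node link count ``k_i`` as an integer array.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    degrees: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise GraphError(f"need at least 2 nodes, got {self.n_nodes}")
        canon = []
        for i, j in self.edges:
            if i == j:
                raise GraphError(f"self-loop at node {i + 1}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise GraphError(f"edge ({i + 1}, {j + 1}) references a missing node")
            canon.append((min(i, j), max(i, j)))
        if len(set(canon)) != len(canon):
            raise GraphError("duplicate edge in edge set")
        object.__setattr__(self, "edges", tuple(sorted(canon)))

        g = self._nx()
        if not nx.is_connected(g):
            comps = [sorted(n + 1 for n in c) for c in nx.connected_components(g)]
            raise GraphError(
                "graph is disconnected; components (1-based): "
                + ", ".join(str(c) for c in comps)
            )
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        if (deg < 1).any():
            raise GraphError("every node needs at least one link")
        deg.setflags(write=False)
        object.__setattr__(self, "degrees", deg)

    def _nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edges_1based(self) -> tuple[tuple[int, int], ...]:
        """Edges with the 1-based labels used in files and reports."""
        return tuple((i + 1, j + 1) for i, j in self.edges)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix A with A[i, j] = 1 iff i-j linked."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def neighbors(self, i: int) -> list[int]:
        """0-based neighbor indices of node ``i`` (0-based)."""
        out = []
        for u, v in self.edges:
            if u == i:
                out.append(v)
            elif v == i:
                out.append(u)
        return sorted(out)


def complete_graph(n: int) -> Graph:
    """Fully linked graph on ``n`` nodes: every degree equals ``n - 1``.

    The archetypal homogeneous network; for n=3 this is the triangle of
    three mutually linked habitats.
    """
    if n < 2:
        raise GraphError(f"complete_graph needs n >= 2, got {n}")
    return Graph(n, tuple((i, j) for i in range(n) for j in range(i + 1, n)))


def path_graph(n: int) -> Graph:
    """Chain of ``n - 1`` links.

    For ``n == 3`` the center is node 1 (labels as printed: links 1-2 and
    1-3), matching the convention that node 1 is the hub through which all
    migration between nodes 2 and 3 must pass.  Larger paths are the plain
    chain 1-2-...-n.
    """
    if n < 2:
        raise GraphError(f"path_graph needs n >= 2, got {n}")
    if n == 3:
        return Graph(3, ((0, 1), (0, 2)))
    return Graph(n, tuple((i, i + 1) for i in range(n - 1)))


def star_graph(n: int) -> Graph:
    """Hub (node 1, degree ``n - 1``) linked to ``n - 1`` leaves (degree 1)."""
    if n < 3:
        raise GraphError(f"star_graph needs n >= 3, got {n}")
    return Graph(n, tuple((0, i) for i in range(1, n)))


def is_homogeneous(g: Graph) -> bool:
    """True iff all node degrees are equal."""
    return bool((g.degrees == g.degrees[0]).all())


def read_edge_list(path) -> Graph:
    """Read a graph from a whitespace-separated edge list.

    One edge per line as two 1-based integer node labels; ``#`` starts a
    comment.  Nodes are 1..max label.  Self-loops, duplicate edges and
    disconnected graphs are rejected.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphError(f"{path}:{lineno}: expected two node labels, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise GraphError(f"{path}:{lineno}: non-integer node label in {line!r}") from None
            if u < 1 or v < 1:
                raise GraphError(f"{path}:{lineno}: node labels are 1-based positive integers")
            if u == v:
                raise GraphError(f"{path}:{lineno}: self-loop at node {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise GraphError(f"{path}:{lineno}: duplicate edge {u} {v}")
            seen.add(key)
            edges.append((u - 1, v - 1))
    if not edges:
        raise GraphError(f"{path}: no edges found")
    n = max(max(e) for e in edges) + 1
    return Graph(n, tuple(edges))


def write_edge_list(g: Graph, path) -> None:
    """Write ``g`` in the same dialect ``read_edge_list`` accepts (1-based)."""
    with open(path, "w") as fh:
        for i, j in g.edges_1based:
            fh.write(f"{i} {j}\n")
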