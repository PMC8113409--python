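"""Minimal undirected simple-graph container used throughout the package.

Graphs here are small and binary: either a graphlet (2-5 nodes) or a
thresholded functional-connectivity network (~100 nodes).  Nodes are the
integers ``0 .. n_nodes-1``; external 1-based atlas labels are attached only
at the I/O boundary.  Adjacency is additionally exposed as Python-integer
bitmasks, which is what makes the pure-Python subgraph enumeration fast.
"""

from __future__ import annotations

from typing import Iterable, Sequence


class GraphError(ValueError):
    """Malformed graph input (self-loop, out-of-range index, ...)."""


class SimpleGraph:
    """Undirected simple graph on nodes ``0..n_nodes-1``.

    Parameters
    ----------
    n_nodes:
        Number of nodes (positive).
    edges:
        Iterable of unordered node pairs.  Duplicates collapse; self-loops
        are rejected.
    """

    __slots__ = ("n_nodes", "edges", "_adj_masks")

    def __init__(self, n_nodes: int, edges: Iterable[tuple[int, int]]):
        if n_nodes < 1:
            raise GraphError(f"n_nodes must be positive, got {n_nodes}")
        self.n_nodes = int(n_nodes)
        norm = set()
        for u, v in edges:
            u, v = int(u), int(v)  # numpy ints would poison the bitmasks
            if u == v:
                raise GraphError(f"self-loop at node {u}")
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise GraphError(f"edge ({u},{v}) outside [0,{n_nodes})")
            norm.add((u, v) if u < v else (v, u))
        self.edges = frozenset(norm)
        self._adj_masks: list[int] | None = None

    # -- basic accessors -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adj_masks(self) -> list[int]:
        """Per-node neighbourhood as an integer bitmask."""
        if self._adj_masks is None:
            masks = [0] * self.n_nodes
            for u, v in self.edges:
                masks[u] |= 1 << v
                masks[v] |= 1 << u
            self._adj_masks = masks
        return self._adj_masks

    def degrees(self) -> list[int]:
        return [m.bit_count() for m in self.adj_masks]

    def has_edge(self, u: int, v: int) -> bool:
        return (self.adj_masks[u] >> v) & 1 == 1

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_adjacency(cls, a) -> "SimpleGraph":
        """Build from a square boolean/0-1 adjacency matrix (diagonal ignored)."""
        n = len(a)
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n) if a[i][j]
        ]
        return cls(n, edges)

    def relabel(self, perm: Sequence[int]) -> "SimpleGraph":
        """Return the graph with node ``i`` renamed to ``perm[i]``."""
        return SimpleGraph(self.n_nodes, [(perm[u], perm[v]) for u, v in self.edges])

    # -- structure -------------------------------------------------------

    def is_connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        masks = self.adj_masks
        seen = 1
        frontier = 1
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & -m
                m ^= b
                nxt |= masks[b.bit_length() - 1]
            frontier = nxt & ~seen
            seen |= nxt
        return seen.bit_count() == self.n_nodes

    def induced(self, nodes: Sequence[int]) -> "SimpleGraph":
        """Induced subgraph on ``nodes``, relabelled 0..k-1 in given order."""
        index = {v: i for i, v in enumerate(nodes)}
        edges = [
            (index[u], index[v])
            for u, v in self.edges
            if u in index and v in index
        ]
        return SimpleGraph(len(nodes), edges)

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimpleGraph)
            and self.n_nodes == other.n_nodes
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.n_nodes, self.edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SimpleGraph(n_nodes={self.n_nodes}, edges={sorted(self.edges)})"
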