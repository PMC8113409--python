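"""The graphlet catalog: all connected graphs on 2-5 nodes and their orbits.

A *graphlet* is a small connected induced subgraph; an *orbit* is an
equivalence class of a graphlet's nodes under its automorphism group.  The
30 graphlets on 2-5 nodes define 73 orbits, conventionally numbered 0-72
(G0 = the edge with orbit 0, G1 = the 3-path with orbits 1 and 2 for
endpoints and midpoint, ... G29 = the 5-clique with orbit 72).  Orbit counts
are partially linearly dependent; only 56 of the 73 orbits carry independent
information and downstream analysis restricts to that list.

The global numbering is a drawing convention, so it is transcribed here as a
hardcoded table (:data:`_CATALOG_TABLE`).  Everything that *can* be derived
is re-derived at build time and checked against the table: the generator
enumerates all connected non-isomorphic graphs on 2-5 nodes from scratch,
recomputes every orbit partition by exhaustive permutation search, and
raises :class:`CatalogIntegrityError` on any mismatch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .graph import GraphError, SimpleGraph

__all__ = [
    "CatalogIntegrityError",
    "Graphlet",
    "OrbitCatalog",
    "NONREDUNDANT_ORBITS",
    "canonical_key",
    "automorphism_orbits",
    "enumerate_connected_graphs",
    "build_catalog",
]


class CatalogIntegrityError(RuntimeError):
    """Generated catalog disagrees with the hardcoded numbering table."""


#: The 56 orbits whose counts are not linear combinations of other orbit
#: counts, in ascending order.  (The complementary redundant set is
#: {3,5,7,14,16,17,20,21,23,26,28,38,44,47,69,71,72}.)
NONREDUNDANT_ORBITS: tuple[int, ...] = (
    0, 1, 2, 4, 6, 8, 9, 10, 11, 12, 13, 15, 18, 19, 22, 24, 25, 27, 29, 30,
    31, 32, 33, 34, 35, 36, 37, 39, 40, 41, 42, 43, 45, 46, 48, 49, 50, 51,
    52, 53, 54, 55, 56, 57, 58, 59, 60, 61, 62, 63, 64, 65, 66, 67, 68, 70,
)

# Pair ordering used by the bit-encoding of adjacency: lexicographic over
# (i, j) with i < j.  Shared by canonical_key and the counting lookup tables.
_PAIRS: dict[int, tuple[tuple[int, int], ...]] = {
    s: tuple(itertools.combinations(range(s), 2)) for s in range(2, 6)
}

# (graphlet id, n_nodes, edges, ((orbit id, nodes), ...)) - the standard
# numbering of the 30 graphlets and 73 orbits.
_CATALOG_TABLE: tuple = (
    (0, 2, ((0, 1),), ((0, (0, 1)),)),
    (1, 3, ((0, 1), (1, 2)), ((1, (0, 2)), (2, (1,)))),
    (2, 3, ((0, 1), (0, 2), (1, 2)), ((3, (0, 1, 2)),)),
    (3, 4, ((0, 1), (1, 2), (2, 3)), ((4, (0, 3)), (5, (1, 2)))),
    (4, 4, ((0, 1), (0, 2), (0, 3)), ((6, (1, 2, 3)), (7, (0,)))),
    (5, 4, ((0, 1), (1, 2), (2, 3), (0, 3)), ((8, (0, 1, 2, 3)),)),
    (6, 4, ((0, 1), (1, 2), (1, 3), (2, 3)),
     ((9, (0,)), (10, (2, 3)), (11, (1,)))),
    (7, 4, ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3)),
     ((12, (2, 3)), (13, (0, 1)))),
    (8, 4, ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)),
     ((14, (0, 1, 2, 3)),)),
    (9, 5, ((0, 1), (1, 2), (2, 3), (3, 4)),
     ((15, (0, 4)), (16, (1, 3)), (17, (2,)))),
    (10, 5, ((0, 1), (1, 2), (2, 3), (2, 4)),
     ((18, (0,)), (19, (3, 4)), (20, (1,)), (21, (2,)))),
    (11, 5, ((0, 1), (0, 2), (0, 3), (0, 4)),
     ((22, (1, 2, 3, 4)), (23, (0,)))),
    (12, 5, ((0, 1), (0, 2), (1, 2), (0, 3), (1, 4)),
     ((24, (3, 4)), (25, (2,)), (26, (0, 1)))),
    (13, 5, ((0, 1), (0, 2), (1, 2), (0, 3), (3, 4)),
     ((27, (4,)), (28, (3,)), (29, (1, 2)), (30, (0,)))),
    (14, 5, ((0, 1), (0, 2), (1, 2), (0, 3), (0, 4)),
     ((31, (3, 4)), (32, (1, 2)), (33, (0,)))),
    (15, 5, ((0, 1), (1, 2), (2, 3), (3, 4), (0, 4)),
     ((34, (0, 1, 2, 3, 4)),)),
    (16, 5, ((0, 1), (1, 2), (2, 3), (0, 3), (0, 4)),
     ((35, (4,)), (36, (1, 3)), (37, (2,)), (38, (0,)))),
    (17, 5, ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (0, 4)),
     ((39, (4,)), (40, (2, 3)), (41, (1,)), (42, (0,)))),
    (18, 5, ((0, 1), (0, 2), (1, 2), (0, 3), (0, 4), (3, 4)),
     ((43, (1, 2, 3, 4)), (44, (0,)))),
    (19, 5, ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 4)),
     ((45, (4,)), (46, (3,)), (47, (0, 1)), (48, (2,)))),
    (20, 5, ((0, 1), (1, 2), (2, 3), (0, 3), (0, 4), (1, 4)),
     ((49, (4,)), (50, (2, 3)), (51, (0, 1)))),
    (21, 5, ((0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)),
     ((52, (2, 3, 4)), (53, (0, 1)))),
    (22, 5, ((0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)),
     ((54, (0, 1, 2)), (55, (3, 4)))),
    (23, 5, ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (0, 4)),
     ((56, (4,)), (57, (1, 2, 3)), (58, (0,)))),
    (24, 5, ((1, 2), (2, 3), (3, 4), (0, 1), (0, 2), (0, 3), (0, 4)),
     ((59, (1, 4)), (60, (2, 3)), (61, (0,)))),
    (25, 5, ((0, 2), (0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4)),
     ((62, (1,)), (63, (3, 4)), (64, (0, 2)))),
    (26, 5, ((0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)),
     ((65, (0,)), (66, (1, 2)), (67, (3, 4)))),
    (27, 5, ((0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 4), (3, 4)),
     ((68, (0, 1, 2, 3)), (69, (4,)))),
    (28, 5, ((0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4),
             (3, 4)),
     ((70, (0, 1)), (71, (2, 3, 4)))),
    (29, 5, ((0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3),
             (2, 4), (3, 4)),
     ((72, (0, 1, 2, 3, 4)),)),
)


def _encode(g: SimpleGraph, perm: tuple[int, ...]) -> int:
    """Bit-encoding of ``g`` relabelled so node ``perm[i]`` becomes ``i``."""
    masks = g.adj_masks
    code = 0
    for bit, (i, j) in enumerate(_PAIRS[g.n_nodes]):
        if (masks[perm[i]] >> perm[j]) & 1:
            code |= 1 << bit
    return code


def canonical_key(g: SimpleGraph) -> int:
    """Canonical integer encoding of a 2-5 node graph.

    The key is the minimum, over all node permutations, of a fixed
    bit-encoding of the adjacency relation, offset by the node count so that
    keys of different sizes never collide.  Two graphs receive the same key
    iff they are isomorphic.
    """
    n = g.n_nodes
    if not 2 <= n <= 5:
        raise GraphError(f"canonical_key needs 2-5 nodes, got {n}")
    best = min(_encode(g, p) for p in itertools.permutations(range(n)))
    return (n << 10) | best


def automorphism_orbits(g: SimpleGraph) -> list[tuple[int, ...]]:
    """Orbit partition of a connected 2-5 node graph.

    Nodes ``u`` and ``v`` share a class iff some automorphism maps ``u`` to
    ``v``.  Computed by exhaustive check of all <=120 permutations.  Classes
    are returned sorted by their smallest member, each class ascending.
    """
    n = g.n_nodes
    if not 2 <= n <= 5:
        raise GraphError(f"automorphism_orbits needs 2-5 nodes, got {n}")
    if not g.is_connected():
        raise GraphError("automorphism_orbits requires a connected graph")
    identity = _encode(g, tuple(range(n)))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in itertools.permutations(range(n)):
        if _encode(g, p) == identity:
            # p is an automorphism of the labelled graph: position i of the
            # relabelled graph carries original node p[i], so i ~ p[i].
            for i in range(n):
                ri, rj = find(i), find(p[i])
                if ri != rj:
                    parent[ri] = rj
    classes: dict[int, list[int]] = {}
    for v in range(n):
        classes.setdefault(find(v), []).append(v)
    return sorted((tuple(sorted(c)) for c in classes.values()), key=lambda c: c[0])


@dataclass(frozen=True)
class Graphlet:
    """One of the 30 canonical graphlets with its orbit structure."""

    id: int
    graph: SimpleGraph
    orbit_partition: tuple[tuple[int, ...], ...]
    orbit_ids: tuple[int, ...]  # global orbit id per partition class

    def orbit_of_node(self, v: int) -> int:
        for cls, oid in zip(self.orbit_partition, self.orbit_ids):
            if v in cls:
                return oid
        raise KeyError(v)


@dataclass(frozen=True)
class OrbitCatalog:
    """The 30 graphlets, the 73-orbit numbering, and the non-redundant list."""

    graphlets: tuple[Graphlet, ...]
    n_orbits: int = 73
    nonredundant: tuple[int, ...] = NONREDUNDANT_ORBITS
    _by_key: dict = field(default_factory=dict, repr=False, compare=False)

    def graphlet_for_key(self, key: int) -> Graphlet:
        """Graphlet whose canonical key is ``key``."""
        return self._by_key[key]

    def orbit_to_graphlet(self, orbit: int) -> Graphlet:
        for gl in self.graphlets:
            if orbit in gl.orbit_ids:
                return gl
        raise KeyError(orbit)


def enumerate_connected_graphs(n: int) -> list[SimpleGraph]:
    """All connected non-isomorphic graphs on ``n`` (2-5) nodes.

    Enumerates every labelled edge set, keeps connected ones, and
    deduplicates by canonical key.  Returned in ascending
    (edge count, canonical key) order - a deterministic order independent of
    the published numbering.
    """
    pairs = _PAIRS[n]
    seen: dict[int, SimpleGraph] = {}
    for bits in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if (bits >> i) & 1]
        g = SimpleGraph(n, edges)
        if not g.is_connected():
            continue
        key = canonical_key(g)
        if key not in seen:
            seen[key] = g
    return sorted(seen.values(), key=lambda g: (g.n_edges, canonical_key(g)))


def build_catalog() -> OrbitCatalog:
    """Generate the catalog and validate it against the hardcoded numbering.

    Raises
    ------
    CatalogIntegrityError
        If the generated structure (graph counts, isomorphism classes, orbit
        partitions, orbit-id bookkeeping) disagrees with the table.
    """
    generated: dict[int, SimpleGraph] = {}
    counts = {}
    for n in range(2, 6):
        graphs = enumerate_connected_graphs(n)
        counts[n] = len(graphs)
        for g in graphs:
            generated[canonical_key(g)] = g
    if counts != {2: 1, 3: 2, 4: 6, 5: 21}:
        raise CatalogIntegrityError(f"unexpected graph counts per size: {counts}")

    graphlets = []
    seen_keys = set()
    seen_orbits: set[int] = set()
    for gid, n, edges, orbit_spec in _CATALOG_TABLE:
        g = SimpleGraph(n, edges)
        key = canonical_key(g)
        if key not in generated:
            raise CatalogIntegrityError(
                f"graphlet G{gid} is not a connected {n}-node graph"
            )
        if key in seen_keys:
            raise CatalogIntegrityError(f"graphlet G{gid} duplicates an earlier entry")
        seen_keys.add(key)
        partition = automorphism_orbits(g)
        table_partition = sorted((tuple(sorted(c)) for _, c in orbit_spec),
                                 key=lambda c: c[0])
        if partition != table_partition:
            raise CatalogIntegrityError(
                f"orbit partition mismatch for G{gid}: generated {partition}, "
                f"table {table_partition}"
            )
        by_class = {tuple(sorted(c)): oid for oid, c in orbit_spec}
        orbit_ids = tuple(by_class[c] for c in partition)
        for oid in orbit_ids:
            if oid in seen_orbits:
                raise CatalogIntegrityError(f"orbit {oid} assigned twice")
            seen_orbits.add(oid)
        graphlets.append(
            Graphlet(id=gid, graph=g, orbit_partition=tuple(partition),
                     orbit_ids=orbit_ids)
        )

    if len(graphlets) != 30:
        raise CatalogIntegrityError(f"expected 30 graphlets, got {len(graphlets)}")
    if seen_orbits != set(range(73)):
        raise CatalogIntegrityError("orbit ids do not cover 0..72 exactly")
    if len(NONREDUNDANT_ORBITS) != 56 or not set(NONREDUNDANT_ORBITS) <= seen_orbits:
        raise CatalogIntegrityError("non-redundant orbit list is malformed")

    catalog = OrbitCatalog(graphlets=tuple(graphlets))
    for gl in graphlets:
        catalog._by_key[canonical_key(gl.graph)] = gl
    return catalog
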