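"""Graphlet degree vectors: per-node orbit counts and their binarization.

``count_gdv`` enumerates every connected induced subgraph on 2-5 nodes
exactly once (ESU: each subgraph is grown from its lowest-index node,
extending only with higher-index exclusive neighbours) and classifies it
through a precomputed labelled-graph -> orbit lookup, so each subgraph costs
a handful of bit operations.  ``count_gdv_bruteforce`` is the independent
oracle: it iterates over all node subsets and classifies each connected one
via canonical form and an explicit isomorphism search.

Counting by explicit enumeration is exact but its cost is the number of
connected <=5-node induced subgraphs, which explodes on dense graphs; the
``max_subgraphs`` guard aborts rather than silently running for hours.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .catalog import _PAIRS, OrbitCatalog, canonical_key
from .graph import GraphError, SimpleGraph

__all__ = [
    "GDVMatrix",
    "BGDVMatrix",
    "GraphTooDenseError",
    "count_gdv",
    "count_gdv_bruteforce",
    "binarize",
]

N_ORBITS = 73


class GraphTooDenseError(RuntimeError):
    """Connected-subgraph count exceeded the configured enumeration cap."""


@dataclass(frozen=True)
class GDVMatrix:
    """Per-node orbit counts: ``values[i, j]`` = times node i touches orbit j.

    ``values`` is n_nodes x 73; column 0 is the node degree.  ``node_labels``
    carries the external (1-based atlas) labels of the rows.
    """

    values: np.ndarray
    node_labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        object.__setattr__(self, "node_labels", np.asarray(self.node_labels))
        if self.values.ndim != 2 or self.values.shape[1] != N_ORBITS:
            raise ValueError(f"GDV matrix must be n x {N_ORBITS}")
        if len(self.node_labels) != self.values.shape[0]:
            raise ValueError("node_labels length mismatch")


@dataclass(frozen=True)
class BGDVMatrix:
    """Binarized GDV restricted to the 56 non-redundant orbits.

    ``values[i, j]`` is 1 iff node i touches the j-th orbit of
    ``orbit_ids`` (the catalog's non-redundant list) at least once.
    """

    values: np.ndarray
    node_labels: np.ndarray
    orbit_ids: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        object.__setattr__(self, "node_labels", np.asarray(self.node_labels))
        if set(np.unique(self.values)) - {0, 1}:
            raise ValueError("BGDV entries must be 0/1")


# ---------------------------------------------------------------------------
# classification lookup: labelled k-node graph code -> orbit id per position
# ---------------------------------------------------------------------------

def _decode_edges(code: int, size: int) -> list[tuple[int, int]]:
    return [p for b, p in enumerate(_PAIRS[size]) if (code >> b) & 1]


def _build_orbit_lookup(catalog: OrbitCatalog) -> list:
    """``table[size][code]`` -> tuple of global orbit ids per node position,
    or None when the labelled graph with that edge-bit code is disconnected."""
    table: list = [None, None]  # sizes 0,1 unused
    for size in range(2, 6):
        n_codes = 1 << len(_PAIRS[size])
        rows: list = [None] * n_codes
        for code in range(n_codes):
            g = SimpleGraph(size, _decode_edges(code, size))
            if not g.is_connected():
                continue
            gl = catalog.graphlet_for_key(canonical_key(g))
            # find one isomorphism g -> gl.graph and push orbits back
            target = gl.graph.adj_masks
            for perm in itertools.permutations(range(size)):
                ok = True
                for u, v in g.edges:
                    if not (target[perm[u]] >> perm[v]) & 1:
                        ok = False
                        break
                if ok and sum(m.bit_count() for m in target) == 2 * g.n_edges:
                    rows[code] = tuple(
                        gl.orbit_of_node(perm[v]) for v in range(size)
                    )
                    break
            if rows[code] is None:  # pragma: no cover - catalog is validated
                raise RuntimeError(f"no isomorphism found for code {code}")
        table.append(rows)
    return table


_LOOKUP_CACHE: dict[int, list] = {}


def _lookup_for(catalog: OrbitCatalog) -> list:
    key = id(catalog)
    if key not in _LOOKUP_CACHE:
        _LOOKUP_CACHE.clear()  # keep at most one catalog's tables around
        _LOOKUP_CACHE[key] = _build_orbit_lookup(catalog)
    return _LOOKUP_CACHE[key]


# ---------------------------------------------------------------------------
# ESU enumeration
# ---------------------------------------------------------------------------

def count_gdv(
    g: SimpleGraph,
    catalog: OrbitCatalog,
    node_labels=None,
    max_subgraphs: int | None = 50_000_000,
) -> GDVMatrix:
    """Count, for every node, how often it touches each of the 73 orbits.

    Every connected induced subgraph on 2-5 nodes is enumerated exactly once;
    each member node's count at its orbit within that subgraph is
    incremented.  Isolated nodes keep all-zero rows (the atlas dimension is
    preserved).

    Parameters
    ----------
    max_subgraphs:
        Abort with :class:`GraphTooDenseError` once more than this many
        subgraphs have been enumerated (None disables the guard).
    """
    n = g.n_nodes
    if node_labels is None:
        node_labels = np.arange(1, n + 1)
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    table = _lookup_for(catalog)
    adj = g.adj_masks
    seen = 0
    cap = max_subgraphs if max_subgraphs is not None else float("inf")

    # local bindings for speed
    t2, t3, t4, t5 = table[2], table[3], table[4], table[5]
    tables = (None, None, t2, t3, t4, t5)

    def classify(sub: tuple) -> None:
        # positions are the insertion order; the lookup covers every
        # labelled ordering, so no canonical sort is needed
        k = len(sub)
        code = 0
        for b, (i, j) in enumerate(_PAIRS[k]):
            if (adj[sub[i]] >> sub[j]) & 1:
                code |= 1 << b
        orbits = tables[k][code]
        for v, o in zip(sub, orbits):
            counts[v, o] += 1

    def extend(sub: tuple, sub_mask: int, nbh_mask: int, ext_mask: int) -> None:
        nonlocal seen
        k = len(sub)
        if k >= 2:
            seen += 1
            if seen > cap:
                raise GraphTooDenseError(
                    f"more than {max_subgraphs} connected subgraphs; raise "
                    "max_subgraphs to proceed"
                )
            classify(sub)
        if k == 5:
            return
        ext = ext_mask
        while ext:
            wbit = ext & -ext
            ext ^= wbit
            w = wbit.bit_length() - 1
            excl = adj[w] & ~(sub_mask | nbh_mask) & root_gt
            extend(sub + (w,), sub_mask | wbit, nbh_mask | adj[w], ext | excl)

    full = (1 << n) - 1
    for v in range(n):
        root_gt = full >> (v + 1) << (v + 1)  # nodes with index > v
        extend((v,), 1 << v, adj[v], adj[v] & root_gt)

    return GDVMatrix(values=counts, node_labels=np.asarray(node_labels))


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def count_gdv_bruteforce(
    g: SimpleGraph, catalog: OrbitCatalog, node_labels=None
) -> GDVMatrix:
    """Oracle counter: iterate over all 2-5 node subsets.

    Keeps subsets whose induced subgraph is connected, finds the catalog
    graphlet by canonical key, maps nodes to orbits through an explicit
    isomorphism, and accumulates.  Guarded to <=15 nodes.
    """
    n = g.n_nodes
    if n > 15:
        raise GraphError(f"brute-force oracle limited to 15 nodes, got {n}")
    if node_labels is None:
        node_labels = np.arange(1, n + 1)
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    memo: dict[tuple[int, int], tuple[int, ...]] = {}

    for k in range(2, min(5, n) + 1):
        for subset in itertools.combinations(range(n), k):
            sub = g.induced(subset)
            if not sub.is_connected():
                continue
            code = (k, _code_of(sub))
            orbits = memo.get(code)
            if orbits is None:
                gl = catalog.graphlet_for_key(canonical_key(sub))
                orbits = _orbits_via_isomorphism(sub, gl)
                memo[code] = orbits
            for v, o in zip(subset, orbits):
                counts[v, o] += 1
    return GDVMatrix(values=counts, node_labels=np.asarray(node_labels))


def _code_of(g: SimpleGraph) -> int:
    code = 0
    for b, (i, j) in enumerate(_PAIRS[g.n_nodes]):
        if g.has_edge(i, j):
            code |= 1 << b
    return code


def _orbits_via_isomorphism(sub: SimpleGraph, gl) -> tuple[int, ...]:
    k = sub.n_nodes
    target = gl.graph
    for perm in itertools.permutations(range(k)):
        if all(target.has_edge(perm[u], perm[v]) for u, v in sub.edges) and \
                sub.n_edges == target.n_edges:
            return tuple(gl.orbit_of_node(perm[v]) for v in range(k))
    raise RuntimeError("no isomorphism found")  # pragma: no cover


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize(gdv: GDVMatrix, catalog: OrbitCatalog) -> BGDVMatrix:
    """Restrict to the non-redundant orbits and map positive counts to 1.

    The result records whether a node touches an orbit at all, which is the
    quantity aggregated across subjects into the frequency table.
    """
    cols = list(catalog.nonredundant)
    values = (gdv.values[:, cols] > 0).astype(np.int64)
    return BGDVMatrix(values=values, node_labels=gdv.node_labels,
                      orbit_ids=tuple(cols))
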