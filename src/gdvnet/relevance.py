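"""The topological-relevance pipeline for connectivity cohorts.

Stages, per subject: keep the positive part of the correlation matrix,
threshold it into a binary graph, count graphlet orbits, binarize.  Cohort
level: sum the binary matrices into the *frequency table* (entry (i, j) =
number of subjects in which node i touches non-redundant orbit j), sort each
column, and scan all column pairs for *set equivalence* of their top entries
at shrinking depths.  Columns that keep sharing the same top node set point
at a small group of nodes that dominate many orbit types across the whole
cohort - in resting-state brain networks these turn out to be default-mode
regions.

The scan works on the first ``r`` rows (top quartile by default).  At step
``k`` (k = 1..r) two columns are equivalent when their top ``r - k + 1`` node
sets coincide as sets; the *output table* entry (j, k) counts the columns
equivalent to column j at step k, the column itself excluded.

Ties
----
The sorted tables break frequency ties by ascending node label, which makes
the tables reproducible but makes a top-``d`` set straddling a tie an
artifact of the tie-break.  Under the default ``tie_policy="exclude"`` a
column does not participate at depth ``d`` when rank d ties with rank d+1,
or when the window reaches zero frequencies (no evidence).  With real,
well-spread frequency tables the policy is almost always a no-op;
``tie_policy="label"`` recovers the plain label-ordered behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .catalog import OrbitCatalog
from .counting import BGDVMatrix, GDVMatrix, binarize, count_gdv
from .graph import SimpleGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "FrequencyTable",
    "SortedTables",
    "OutputTable",
    "CohortError",
    "positive_part",
    "threshold_binarize",
    "subject_bgdv",
    "frequency_table",
    "sort_tables",
    "column_equivalence_scan",
    "equivalence_groups",
    "persistent_nodes",
    "default_row_budget",
]

SYMMETRY_ATOL = 1e-9


class CohortError(ValueError):
    """Inconsistent cohort input (shape mismatch, duplicate ids, ...)."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Square symmetric functional-connectivity matrix, entries in [-1, 1]."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise CohortError(f"connectivity matrix must be square, got {v.shape}")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise CohortError("connectivity entries must lie in [-1, 1]")
        if not np.allclose(v, v.T, atol=SYMMETRY_ATOL, rtol=0):
            raise CohortError(
                f"matrix for subject {self.subject_id!r} is not symmetric"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def positive_part(F: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero out negative correlations (keep only the positive network F+)."""
    return ConnectivityMatrix(values=np.maximum(F.values, 0.0),
                              subject_id=F.subject_id)


def threshold_binarize(Fp: ConnectivityMatrix, t: float) -> SimpleGraph:
    """Binary graph with an edge wherever the weight is >= t (diagonal ignored).

    At ``t = 0`` an edge additionally requires a strictly positive weight,
    so that the zeros produced by :func:`positive_part` never become edges.
    """
    if t < 0:
        raise ValueError(f"threshold must be non-negative, got {t}")
    v = Fp.values
    keep = (v >= t) & (v > 0)
    n = Fp.n_nodes
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if keep[i, j]]
    return SimpleGraph(n, edges)


def subject_bgdv(
    F: ConnectivityMatrix,
    t: float,
    catalog: OrbitCatalog,
    node_labels=None,
    max_subgraphs: int | None = 50_000_000,
) -> BGDVMatrix:
    """Convenience: positive part -> threshold -> GDV -> binarize."""
    g = threshold_binarize(positive_part(F), t)
    gdv = count_gdv(g, catalog, node_labels=node_labels,
                    max_subgraphs=max_subgraphs)
    return binarize(gdv, catalog)


@dataclass(frozen=True)
class FrequencyTable:
    """Cohort sum of binary GDV matrices; entries in [0, n_subjects]."""

    values: np.ndarray
    node_labels: np.ndarray
    orbit_ids: tuple[int, ...]
    n_subjects: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        object.__setattr__(self, "node_labels", np.asarray(self.node_labels))
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > self.n_subjects:
            raise CohortError("frequency entries must lie in [0, n_subjects]")


def frequency_table(bgdvs: list[BGDVMatrix]) -> FrequencyTable:
    """Elementwise sum of the subjects' binary GDV matrices."""
    if not bgdvs:
        raise CohortError("empty cohort")
    first = bgdvs[0]
    for b in bgdvs[1:]:
        if b.values.shape != first.values.shape or \
                not np.array_equal(b.node_labels, first.node_labels) or \
                b.orbit_ids != first.orbit_ids:
            raise CohortError("subject BGDV matrices are not aligned")
    total = np.sum([b.values for b in bgdvs], axis=0)
    return FrequencyTable(values=total, node_labels=first.node_labels,
                          orbit_ids=first.orbit_ids, n_subjects=len(bgdvs))


@dataclass(frozen=True)
class SortedTables:
    """Columnwise-sorted frequency table plus the node provenance table.

    ``sorted_freq[:, j]`` is column j of the frequency table in
    non-increasing order (ties broken by ascending node label);
    ``sorted_nodes[i, j]`` is the label of the node whose frequency landed
    at rank i of column j.
    """

    sorted_freq: np.ndarray
    sorted_nodes: np.ndarray
    orbit_ids: tuple[int, ...]
    n_subjects: int


def sort_tables(M_f: FrequencyTable) -> SortedTables:
    """Sort each column individually, recording node provenance."""
    freq = M_f.values
    labels = np.asarray(M_f.node_labels)
    n, m = freq.shape
    sorted_freq = np.empty_like(freq)
    sorted_nodes = np.empty((n, m), dtype=labels.dtype)
    for j in range(m):
        order = np.lexsort((labels, -freq[:, j]))
        sorted_freq[:, j] = freq[order, j]
        sorted_nodes[:, j] = labels[order]
    return SortedTables(sorted_freq=sorted_freq, sorted_nodes=sorted_nodes,
                        orbit_ids=M_f.orbit_ids, n_subjects=M_f.n_subjects)


@dataclass(frozen=True)
class OutputTable:
    """Column-equivalence counts: entry (j, k) = number of other columns
    whose top-(r-k+1) node set equals column j's, at step k = 1..r."""

    values: np.ndarray  # n_orbits x r
    r: int
    orbit_ids: tuple[int, ...]
    tie_policy: str = "exclude"
    cumulative: bool = False

    def earliest_step(self) -> int | None:
        """Smallest k with any nonzero entry, or None for an all-zero table."""
        nz = np.nonzero(self.values.any(axis=0))[0]
        return int(nz[0]) + 1 if nz.size else None


def default_row_budget(n_nodes: int) -> int:
    """Top-quartile row budget r (24 for the 94-node atlas)."""
    return int(np.ceil(n_nodes / 4))


def _column_topsets(T: SortedTables, depth: int, tie_policy: str):
    """Top-``depth`` node set per column, or None where the column does not
    participate at this depth under the tie policy."""
    n, m = T.sorted_freq.shape
    out = []
    for j in range(m):
        col = T.sorted_freq[:, j]
        if tie_policy == "exclude":
            if col[depth - 1] <= 0:
                out.append(None)
                continue
            if depth < n and col[depth - 1] == col[depth]:
                out.append(None)
                continue
        out.append(frozenset(T.sorted_nodes[:depth, j].tolist()))
    return out


def column_equivalence_scan(
    T: SortedTables,
    r: int | None = None,
    tie_policy: str = "exclude",
    cumulative: bool = False,
) -> OutputTable:
    """Scan all column pairs for top-set equivalence at steps k = 1..r.

    At step k the comparison depth is ``r - k + 1`` rows.  With
    ``cumulative=True`` a pair once equivalent stays counted at all later
    steps (monotone closure); the default is the strict per-step relation.
    """
    n, m = T.sorted_freq.shape
    if r is None:
        r = default_row_budget(n)
    if not 1 <= r <= n:
        raise ValueError(f"row budget r={r} outside [1, {n}]")
    if tie_policy not in ("exclude", "label"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    values = np.zeros((m, r), dtype=np.int64)
    pair_seen = np.zeros((m, m), dtype=bool) if cumulative else None
    for k in range(1, r + 1):
        depth = r - k + 1
        tops = _column_topsets(T, depth, tie_policy)
        groups: dict[frozenset, list[int]] = {}
        for j, s in enumerate(tops):
            if s is not None:
                groups.setdefault(s, []).append(j)
        if cumulative:
            for cols in groups.values():
                for a in cols:
                    for b in cols:
                        if a != b:
                            pair_seen[a, b] = True
            values[:, k - 1] = pair_seen.sum(axis=1)
        else:
            for cols in groups.values():
                if len(cols) > 1:
                    for j in cols:
                        values[j, k - 1] = len(cols) - 1
    return OutputTable(values=values, r=r, orbit_ids=T.orbit_ids,
                       tie_policy=tie_policy, cumulative=cumulative)


def equivalence_groups(
    T: SortedTables,
    r: int,
    k: int,
    tie_policy: str = "exclude",
) -> list[tuple[tuple[int, ...], frozenset]]:
    """Maximal groups of columns with identical top-(r-k+1) node sets.

    Returns (orbit-id group, shared node set) pairs; singleton groups are
    omitted.  Groups are sorted by their first orbit id.
    """
    if not 1 <= k <= r:
        raise ValueError(f"step k={k} outside [1, {r}]")
    depth = r - k + 1
    tops = _column_topsets(T, depth, tie_policy)
    groups: dict[frozenset, list[int]] = {}
    for j, s in enumerate(tops):
        if s is not None:
            groups.setdefault(s, []).append(j)
    out = []
    for s, cols in groups.items():
        if len(cols) > 1:
            out.append((tuple(T.orbit_ids[j] for j in cols), s))
    return sorted(out, key=lambda item: item[0])


def persistent_nodes(
    scans: dict[float, tuple[OutputTable, SortedTables]],
    r: int | None = None,
) -> dict:
    """Cross-threshold persistence report.

    For each threshold, find the earliest step with any column equivalence
    and collect the node sets shared by the groups at that step; the
    *persistent* set is the intersection of those per-threshold sets.
    Thresholds whose output table is all-zero are reported as
    ``no equivalence found`` and excluded from the intersection.
    """
    if not scans:
        raise ValueError("at least one threshold is required")
    report: dict = {"thresholds": {}, "persistent": None}
    intersect: set | None = None
    for t in sorted(scans):
        table, sorted_tables = scans[t]
        r_t = table.r if r is None else r
        k = table.earliest_step()
        entry: dict = {"r": r_t}
        if k is None:
            logger.warning("threshold %s: no column equivalence found; "
                           "excluded from the persistent intersection", t)
            entry.update({"earliest_step": None, "groups": [],
                          "nodes": [], "note": "no equivalence found"})
        else:
            groups = equivalence_groups(sorted_tables, r_t, k,
                                        tie_policy=table.tie_policy)
            nodes: set = set()
            for _, shared in groups:
                nodes |= shared
            entry.update({
                "earliest_step": k,
                "depth": r_t - k + 1,
                "groups": [
                    {"orbits": list(orbits), "nodes": sorted(shared)}
                    for orbits, shared in groups
                ],
                "nodes": sorted(nodes),
            })
            intersect = set(nodes) if intersect is None else intersect & nodes
        report["thresholds"][t] = entry
    report["persistent"] = sorted(intersect) if intersect is not None else []
    return report
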