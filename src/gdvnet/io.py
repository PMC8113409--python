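"""Readers, writers and run records.

External conventions: matrices are square delimited numeric text (comma,
tab or whitespace, auto-detected); the subject manifest is a TSV with
columns ``subject_id``, ``matrix_path`` and optional ``sex``/``age``; all
tables are written as TSV; node identifiers are 1-based atlas labels in
every file, 0-based indices internally.  Every pipeline run can write a JSON
run record (package version, configuration, seeds, input digests) so that a
result can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .relevance import (ConnectivityMatrix, FrequencyTable, OutputTable,
                        SortedTables)

logger = logging.getLogger(__name__)

__all__ = [
    "ManifestError",
    "read_connectivity",
    "read_manifest",
    "load_cohort",
    "write_matrix",
    "write_cohort",
    "write_frequency_table",
    "write_sorted_tables",
    "write_output_table",
    "write_json",
    "newick_from_linkage",
    "write_run_record",
]

_SOFT_ATOL = 1e-6
_HARD_ATOL = 1e-9


class ManifestError(ValueError):
    """Bad subject manifest (duplicate ids, missing files, ...)."""


def read_connectivity(path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Parse one square connectivity matrix from delimited text.

    Delimiters are auto-detected (comma vs tab/whitespace).  Asymmetry up to
    1e-9 is accepted as-is; up to 1e-6 the matrix is symmetrized by
    averaging with a warning; beyond that it is an error, as are non-square
    shapes and entries outside [-1, 1].
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: not a numeric matrix: {exc}") from exc
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is {values.shape}, expected square")
    if np.abs(values).max() > 1 + 1e-12:
        raise ValueError(f"{path}: entries outside [-1, 1]")
    if not np.allclose(values, values.T, atol=_HARD_ATOL, rtol=0):
        if np.allclose(values, values.T, atol=_SOFT_ATOL, rtol=0):
            logger.warning("%s: asymmetry within 1e-6; symmetrized by averaging",
                           path)
            values = (values + values.T) / 2.0
        else:
            raise ValueError(f"{path}: matrix is badly asymmetric")
    return ConnectivityMatrix(values=values,
                              subject_id=subject_id or path.stem)


def read_manifest(path) -> pd.DataFrame:
    """Read the subject manifest TSV and resolve matrix paths.

    Requires ``subject_id`` and ``matrix_path`` columns; ``sex`` and ``age``
    are optional and may be empty (such subjects are skipped by attribute
    tests, with a warning, not by the topological pipeline).  Paths are
    resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = {"subject_id", "matrix_path"} - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestError(f"{path}: duplicate subject ids {dups}")
    base = path.parent
    df["matrix_path"] = [
        str(p if (p := Path(mp)).is_absolute() else base / mp)
        for mp in df["matrix_path"]
    ]
    unresolved = [p for p in df["matrix_path"] if not Path(p).exists()]
    if unresolved:
        raise ManifestError(f"{path}: unreadable matrix paths {unresolved[:3]}")
    return df


def load_cohort(manifest: pd.DataFrame) -> list[tuple[str, ConnectivityMatrix]]:
    return [
        (row.subject_id, read_connectivity(row.matrix_path, row.subject_id))
        for row in manifest.itertuples()
    ]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(path, values: np.ndarray, fmt: str = "%.12g") -> None:
    np.savetxt(path, values, fmt=fmt, delimiter="\t")


def write_cohort(outdir, matrices, manifest: pd.DataFrame) -> Path:
    """Write one matrix file per subject plus ``manifest.tsv``; returns it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in matrices:
        p = outdir / f"{m.subject_id}.tsv"
        write_matrix(p, m.values)
        paths.append(p.name)
    out = manifest.copy()
    out.insert(1, "matrix_path", paths)
    mpath = outdir / "manifest.tsv"
    out.to_csv(mpath, sep="\t", index=False)
    return mpath


def _orbit_cols(orbit_ids) -> list[str]:
    return [f"O{o}" for o in orbit_ids]


def write_frequency_table(path, table: FrequencyTable) -> None:
    df = pd.DataFrame(table.values, columns=_orbit_cols(table.orbit_ids))
    df.insert(0, "node", table.node_labels)
    df.to_csv(path, sep="\t", index=False)


def write_sorted_tables(outdir, tables: SortedTables) -> None:
    outdir = Path(outdir)
    cols = _orbit_cols(tables.orbit_ids)
    pd.DataFrame(tables.sorted_freq, columns=cols).to_csv(
        outdir / "sorted_frequency.tsv", sep="\t", index=False)
    pd.DataFrame(tables.sorted_nodes, columns=cols).to_csv(
        outdir / "sorted_nodes.tsv", sep="\t", index=False)


def write_output_table(path, table: OutputTable) -> None:
    df = pd.DataFrame(table.values,
                      columns=[f"k{k}" for k in range(1, table.r + 1)])
    df.insert(0, "orbit", [f"O{o}" for o in table.orbit_ids])
    df.to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(_stringify_keys(obj), indent=2,
                                     default=default) + "\n")


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def newick_from_linkage(Z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick tree.

    Branch lengths are the differences between a cluster's merge height and
    its children's heights (leaves sit at height 0).
    """
    Z = np.asarray(Z)
    n = Z.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return str(leaf_names[node])
        li, ri, h = int(Z[node - n, 0]), int(Z[node - n, 1]), float(Z[node - n, 2])
        heights[node] = h
        left = render(li)
        right = render(ri)
        return (f"({left}:{h - heights[li]:.10g},"
                f"{right}:{h - heights[ri]:.10g})")

    return render(2 * n - 2) + ";"


def write_run_record(path, config: dict, input_paths=(), seed=None) -> None:
    """JSON record of a run: version, config, seed, input digests."""
    digests = {}
    for p in input_paths:
        p = Path(p)
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    write_json(path, {
        "package": "gdvnet",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_sha256": digests,
    })
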