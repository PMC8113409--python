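"""Network comparison via graphlet correlation distance (GCD).

Each subject's network is summarized by its *graphlet correlation matrix*
(GCM): the 56 x 56 Spearman correlation matrix between the non-redundant
orbit-count columns of the GDV matrix.  Rank correlation is used because
orbit counts live on wildly different scales.  The distance between two
networks is the Euclidean distance between the strict upper triangles of
their GCMs (56*55/2 = 1540 coordinates), which makes the subject-by-subject
GCD matrix an exact Euclidean metric.

Cohort structure is then explored with agglomerative clustering under Ward's
criterion (appropriate for Euclidean distances), validated by the silhouette
score s_i = (b_i - a_i) / max(a_i, b_i), and related to subject attributes
with an exact binomial test and a label-permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom, spearmanr

from .catalog import OrbitCatalog
from .counting import GDVMatrix, binarize

logger = logging.getLogger(__name__)

__all__ = [
    "GCMatrix",
    "GCDMatrix",
    "ClusterResult",
    "AssociationResult",
    "gcm",
    "gcd_pair",
    "gcd_matrix",
    "ward_cluster",
    "silhouette",
    "binomial_association",
    "permutation_association",
]


@dataclass(frozen=True)
class GCMatrix:
    """Per-subject orbit-orbit Spearman correlation matrix (unit diagonal)."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GCM must be square")


@dataclass(frozen=True)
class GCDMatrix:
    """Subject-by-subject Euclidean distances between GCM upper triangles."""

    values: np.ndarray
    subject_ids: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class ClusterResult:
    """Ward merge history, a flat cut, and its silhouette validation."""

    linkage: np.ndarray          # scipy linkage matrix
    labels: np.ndarray           # cluster id (1..n_clusters) per subject
    silhouettes: np.ndarray      # s_i per subject
    cluster_means: dict          # cluster id -> mean s_i
    overall_mean: float
    subject_ids: tuple[str, ...]


@dataclass(frozen=True)
class AssociationResult:
    test: str
    statistic: float
    p_value: float
    n_permutations: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# GCM / GCD
# ---------------------------------------------------------------------------

def gcm(gdv: GDVMatrix, catalog: OrbitCatalog, mode: str = "counts") -> GCMatrix:
    """Spearman correlation matrix between non-redundant orbit columns.

    ``mode="counts"`` (default) correlates the raw orbit counts;
    ``mode="binary"`` correlates the 0/1 touch indicators.  Correlations
    involving a constant column are undefined and set to 0 with a warning;
    the diagonal is forced to 1.
    """
    if gdv.values.shape[0] < 3:
        raise ValueError("GCM needs at least 3 nodes")
    if mode == "counts":
        X = gdv.values[:, list(catalog.nonredundant)].astype(float)
    elif mode == "binary":
        X = binarize(gdv, catalog).values.astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X).statistic
        rho = np.asarray(rho, dtype=float)
        if rho.shape != (X.shape[1], X.shape[1]):
            # scipy collapses to a scalar in heavily degenerate cases;
            # fall back to ranking the columns explicitly
            from scipy.stats import rankdata
            ranks = np.column_stack([rankdata(X[:, j])
                                     for j in range(X.shape[1])])
            rho = np.corrcoef(ranks, rowvar=False)
    n_bad = int(np.isnan(rho).sum())
    if n_bad:
        const = int((X.std(axis=0) == 0).sum())
        logger.warning(
            "GCM: %d correlations involve constant orbit columns (%d columns); "
            "set to 0", n_bad, const)
        rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return GCMatrix(values=rho, subject_id=getattr(gdv, "subject_id", ""))


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(values, k=1)
    return values[iu]


def gcd_pair(A, B) -> float:
    """Euclidean distance between the strict upper triangles of two GCMs."""
    a = A.values if isinstance(A, GCMatrix) else np.asarray(A, dtype=float)
    b = B.values if isinstance(B, GCMatrix) else np.asarray(B, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"GCM shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(_upper(a) - _upper(b)))


def gcd_matrix(gcms: list[GCMatrix], subject_ids=None) -> GCDMatrix:
    """All pairwise graphlet correlation distances for a cohort."""
    if len(gcms) < 2:
        raise ValueError("need at least 2 subjects")
    if subject_ids is None:
        subject_ids = tuple(g.subject_id or str(i) for i, g in enumerate(gcms))
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    X = np.stack([_upper(g.values) for g in gcms])
    D = squareform(pdist(X, metric="euclidean"))
    return GCDMatrix(values=D, subject_ids=tuple(subject_ids))


# ---------------------------------------------------------------------------
# clustering + validation
# ---------------------------------------------------------------------------

def ward_cluster(D: GCDMatrix, n_clusters: int = 2) -> ClusterResult:
    """Agglomerative clustering of the GCD matrix under Ward's criterion.

    The merge history follows the Lance-Williams recurrence on the supplied
    distances (they are Euclidean in the GCM upper-triangle embedding, so
    Ward's variance interpretation applies).  Labels come from cutting the
    dendrogram into ``n_clusters`` groups and are renumbered 1..n_clusters
    in order of first appearance.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > D.n_subjects:
        raise ValueError("n_clusters exceeds the number of subjects")
    Z = linkage(D.condensed(), method="ward")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, c in enumerate(raw):
        labels[i] = remap.setdefault(c, len(remap) + 1)
    s, means, overall = silhouette(D, labels)
    return ClusterResult(linkage=Z, labels=labels, silhouettes=s,
                         cluster_means=means, overall_mean=overall,
                         subject_ids=D.subject_ids)


def silhouette(D: GCDMatrix, labels) -> tuple[np.ndarray, dict, float]:
    """Per-subject silhouette values s_i = (b_i - a_i)/max(a_i, b_i).

    a_i is the mean distance to the other members of i's cluster; b_i the
    smallest, over other clusters, of the mean distance to that cluster.
    Members of singleton clusters get s_i = 0.  Returns the per-subject
    values, per-cluster means, and the overall mean.
    """
    labels = np.asarray(labels)
    d = D.values
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a_i = d[i, own].sum() / (n_own - 1)
        b_i = min(d[i, labels == c].mean() for c in clusters if c != labels[i])
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    means = {int(c): float(s[labels == c].mean()) for c in clusters}
    return s, means, float(s.mean())


# ---------------------------------------------------------------------------
# cluster-attribute association
# ---------------------------------------------------------------------------

def binomial_association(labels, attribute, cluster_id) -> AssociationResult:
    """Exact two-sided binomial test of a cluster's attribute enrichment.

    The count of attribute-positive members of the cluster is tested against
    the whole-sample proportion; the two-sided p doubles the smaller tail
    (point included), capped at 1.
    """
    labels = np.asarray(labels)
    attribute = np.asarray(attribute)
    in_cluster = labels == cluster_id
    n = int(in_cluster.sum())
    if n == 0:
        raise ValueError(f"cluster {cluster_id!r} is empty")
    vals = set(np.unique(attribute).tolist())
    if not vals <= {0, 1}:
        raise ValueError("attribute must be binary 0/1")
    if np.any(attribute[in_cluster] < 0):  # pragma: no cover - defensive
        raise ValueError("missing attribute values in cluster")
    x = int(attribute[in_cluster].sum())
    p0 = float(attribute.mean())
    lower = float(binom.cdf(x, n, p0))
    upper = float(binom.sf(x - 1, n, p0))
    p = min(1.0, 2.0 * min(lower, upper))
    return AssociationResult(test="binomial", statistic=float(x), p_value=p)


def permutation_association(labels, attribute, n_perm: int = 1000,
                            seed: int = 0) -> AssociationResult:
    """Permutation test of attribute imbalance between two clusters.

    Statistic: |proportion of attribute=1 in cluster 1 - proportion in
    cluster 2|.  The attribute vector is permuted across subjects with a
    seeded generator; p uses the add-one rule
    (1 + #{permuted >= observed}) / (1 + n_perm), so p >= 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    attribute = np.asarray(attribute, dtype=float)
    clusters = np.unique(labels)
    if clusters.size != 2:
        raise ValueError("permutation test expects exactly 2 clusters")
    if np.all(attribute == attribute[0]):
        raise ValueError("attribute is constant; test is degenerate")
    m1 = labels == clusters[0]
    m2 = labels == clusters[1]

    def stat(a: np.ndarray) -> float:
        return abs(a[m1].mean() - a[m2].mean())

    observed = stat(attribute)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(attribute, (n_perm, 1)), axis=1)
    null = np.abs(perms[:, m1].mean(axis=1) - perms[:, m2].mean(axis=1))
    p = (1.0 + float((null >= observed - 1e-15).sum())) / (1.0 + n_perm)
    return AssociationResult(test="permutation", statistic=float(observed),
                             p_value=p, n_permutations=n_perm, seed=seed)
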