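"""GCM/GCD, Ward clustering, silhouettes, association tests."""

import numpy as np
import pytest
from scipy.stats import rankdata

from gdvnet.comparison import (GCDMatrix, GCMatrix, binomial_association,
                               gcd_matrix, gcd_pair, gcm,
                               permutation_association, silhouette,
                               ward_cluster)
from gdvnet.counting import GDVMatrix, count_gdv
from gdvnet.relevance import positive_part, threshold_binarize
from gdvnet.synthetic import SyntheticConfig, generate_cohort


def gdv_from(values):
    values = np.asarray(values)
    full = np.zeros((values.shape[0], 73), dtype=int)
    full[:, :values.shape[1]] = values
    return GDVMatrix(values=full, node_labels=np.arange(1, len(values) + 1))


class TestGCM:
    def test_identical_columns_correlate_one(self, catalog):
        m = gdv_from([[1, 1], [2, 2], [3, 3], [5, 5]])
        out = gcm(m, catalog)
        assert out.values[0, 1] == pytest.approx(1.0)

    def test_decreasing_transform_correlates_minus_one(self, catalog):
        m = gdv_from([[1, 9], [2, 5], [3, 2], [4, 1]])
        out = gcm(m, catalog)
        assert out.values[0, 1] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, catalog, rng):
        vals = rng.integers(0, 30, size=(6, 73))
        m = GDVMatrix(values=vals, node_labels=np.arange(1, 7))
        out = gcm(m, catalog)
        X = vals[:, list(catalog.nonredundant)]
        ranks = np.column_stack([rankdata(X[:, j]) for j in range(56)])
        keep = ranks.std(axis=0) > 0
        oracle = np.corrcoef(ranks, rowvar=False)
        np.testing.assert_allclose(out.values[np.ix_(keep, keep)],
                                   oracle[np.ix_(keep, keep)], atol=1e-12)

    def test_constant_column_zeroed_with_warning(self, catalog, caplog):
        m = gdv_from([[1, 0], [2, 0], [3, 0], [4, 0]])
        import logging
        logger = logging.getLogger("gdvnet.comparison")
        old = logger.level
        logger.setLevel(logging.WARNING)
        try:
            with caplog.at_level("WARNING", logger="gdvnet.comparison"):
                out = gcm(m, catalog)
        finally:
            logger.setLevel(old)
        assert out.values[0, 1] == 0.0
        assert out.values[1, 1] == 1.0  # diagonal forced
        assert "constant orbit columns" in caplog.text

    def test_too_few_nodes(self, catalog):
        with pytest.raises(ValueError):
            gcm(gdv_from([[1], [2]]), catalog)


class TestGCD:
    def test_hand_example_sqrt032(self):
        A = np.array([[1, 0.5, 0.2], [0.5, 1, 0.1], [0.2, 0.1, 1]])
        B = np.array([[1, 0.1, 0.2], [0.1, 1, 0.5], [0.2, 0.5, 1]])
        assert gcd_pair(A, B) == pytest.approx(np.sqrt(0.32), abs=1e-12)
        assert gcd_pair(A, B) == gcd_pair(B, A)
        assert gcd_pair(A, A) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gcd_pair(np.eye(3), np.eye(4))

    def test_matrix_is_a_metric(self, rng):
        gcms = [GCMatrix(values=_random_gcm(rng), subject_id=f"s{i}")
                for i in range(8)]
        D = gcd_matrix(gcms).values
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all()
        n = len(D)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_duplicate_ids_rejected(self, rng):
        g = GCMatrix(values=_random_gcm(rng), subject_id="same")
        with pytest.raises(ValueError):
            gcd_matrix([g, g])


def _random_gcm(rng, m=10):
    a = rng.uniform(-1, 1, size=(m, m))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def _ward_oracle(D):
    """Naive Lance-Williams Ward agglomeration on a distance matrix."""
    n = len(D)
    d2 = D.astype(float) ** 2
    active = {i: ([i], i) for i in range(n)}  # id -> (members, linkage index)
    d = {frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = []
    next_id = n
    sizes = {i: 1 for i in range(n)}
    while len(active) > 1:
        (i, j), val = min(d.items(), key=lambda kv: (kv[1], sorted(kv[0])))
        i, j = sorted(i for i in (i, j))
        Z.append([active[i][1], active[j][1], np.sqrt(val),
                  sizes[i] + sizes[j]])
        merged = active[i][0] + active[j][0]
        for k in list(active):
            if k in (i, j):
                continue
            nik, njk, nk = sizes[i], sizes[j], sizes[k]
            tot = nik + njk + nk
            new = ((nik + nk) * d[frozenset((i, k))]
                   + (njk + nk) * d[frozenset((j, k))]
                   - nk * d[frozenset((i, j))]) / tot
            d[frozenset((i, k))] = new
            del d[frozenset((j, k))]
        del d[frozenset((i, j))]
        sizes[i] = sizes[i] + sizes[j]
        active[i] = (merged, next_id)
        del active[j]
        next_id += 1
    return np.array(Z)


class TestWard:
    def test_matches_lance_williams_oracle(self, rng):
        pts = rng.normal(size=(9, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        gd = GCDMatrix(values=D, subject_ids=tuple(map(str, range(9))))
        res = ward_cluster(gd, 3)
        oracle = _ward_oracle(D)
        np.testing.assert_allclose(res.linkage[:, 2], oracle[:, 2], rtol=1e-9)
        np.testing.assert_allclose(np.sort(res.linkage[:, :2], axis=1),
                                   np.sort(oracle[:, :2], axis=1))

    def test_two_blobs_recovered(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, size=(5, 2)),
                         rng.normal(10, 0.05, size=(6, 2))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        gd = GCDMatrix(values=D, subject_ids=tuple(map(str, range(11))))
        res = ward_cluster(gd, 2)
        assert len(set(res.labels[:5])) == 1
        assert len(set(res.labels[5:])) == 1
        assert res.labels[0] != res.labels[-1]
        assert res.overall_mean > 0.9

    def test_first_merge_is_closest_pair(self):
        D = np.array([[0.0, 1.0, 8.0], [1.0, 0.0, 9.0], [8.0, 9.0, 0.0]])
        gd = GCDMatrix(values=D, subject_ids=("a", "b", "c"))
        res = ward_cluster(gd, 2)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_too_many_clusters(self):
        gd = GCDMatrix(values=np.zeros((3, 3)), subject_ids=("a", "b", "c"))
        with pytest.raises(ValueError):
            ward_cluster(gd, 4)


class TestSilhouette:
    def test_three_point_worked_example(self):
        D = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        gd = GCDMatrix(values=D, subject_ids=("a", "b", "c"))
        s, means, overall = silhouette(gd, [1, 1, 2])
        assert s[0] == pytest.approx(0.9)
        assert s[2] == 0.0  # singleton convention
        assert means[1] == pytest.approx(0.9)
        assert overall == pytest.approx((0.9 + 0.9 + 0.0) / 3)

    def test_equal_a_and_b_gives_zero(self):
        D = np.array([
            [0, 2, 2, 2], [2, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]
        ], dtype=float)
        gd = GCDMatrix(values=D, subject_ids=tuple("abcd"))
        s, _, _ = silhouette(gd, [1, 1, 2, 2])
        np.testing.assert_allclose(s, 0.0)

    def test_matches_sklearn_on_nondegenerate(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        pts = rng.normal(size=(12, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array([1] * 6 + [2] * 6)
        gd = GCDMatrix(values=D, subject_ids=tuple(map(str, range(12))))
        s, _, _ = silhouette(gd, labels)
        ref = sklearn.silhouette_samples(D, labels, metric="precomputed")
        np.testing.assert_allclose(s, ref, atol=1e-12)

    def test_single_cluster_rejected(self):
        gd = GCDMatrix(values=np.zeros((3, 3)), subject_ids=("a", "b", "c"))
        with pytest.raises(ValueError):
            silhouette(gd, [1, 1, 1])


class TestBinomial:
    def test_worked_tail_example(self):
        labels = np.array([1] * 10 + [2] * 10)
        attr = np.concatenate([np.ones(9), [0], np.ones(1), np.zeros(9)])
        # overall proportion 0.5; cluster 1 has 9/10 positives
        res = binomial_association(labels, attr.astype(int), 1)
        assert res.p_value == pytest.approx(2 * 11 / 1024)

    def test_exact_null_proportion_capped_at_one(self):
        labels = np.array([1] * 4 + [2] * 4)
        attr = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        res = binomial_association(labels, attr, 1)
        assert res.p_value == 1.0

    def test_monotone_in_deviation(self):
        labels = np.array([1] * 10 + [2] * 10)
        pvals = []
        for x in range(5, 11):
            attr = np.zeros(20, dtype=int)
            attr[:x] = 1           # x positives in cluster 1
            attr[10:10 + (10 - x)] = 1  # keep overall proportion at 0.5
            res = binomial_association(labels, attr, 1)
            pvals.append(res.p_value)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            binomial_association(np.array([1, 1]), np.array([0, 1]), 3)


class TestPermutation:
    def test_perfect_separation_hits_addone_floor(self):
        labels = np.array([1] * 8 + [2] * 8)
        attr = (labels == 1).astype(int)
        res = permutation_association(labels, attr, n_perm=1000, seed=5)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_addone_lower_bound(self, rng):
        labels = np.array([1] * 6 + [2] * 6)
        for _ in range(5):
            attr = rng.integers(0, 2, size=12)
            if attr.min() == attr.max():
                continue
            res = permutation_association(labels, attr, n_perm=99, seed=3)
            assert res.p_value >= 1 / 100

    def test_seed_determinism(self):
        labels = np.array([1] * 6 + [2] * 6)
        attr = np.array([1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0, 0])
        p1 = permutation_association(labels, attr, 500, seed=11).p_value
        p2 = permutation_association(labels, attr, 500, seed=11).p_value
        assert p1 == p2

    def test_constant_attribute_rejected(self):
        labels = np.array([1, 1, 2, 2])
        with pytest.raises(ValueError):
            permutation_association(labels, np.ones(4), 10, seed=0)


def test_synthetic_two_population_pipeline_recovers_split(catalog):
    """End-to-end: GCMs separate a density-shifted subpopulation."""
    sklearn = pytest.importorskip("sklearn.metrics")
    cfg = SyntheticConfig(n_nodes=18, n_subjects=20,
                          core_nodes=(1, 4, 8, 12, 15, 18), noise_sd=0.05,
                          populations=((0.5, 0.0, 0.0), (0.5, 0.15, 0.0)),
                          seed=21)
    mats, manifest = generate_cohort(cfg)
    gcms = []
    for F in mats:
        g = threshold_binarize(positive_part(F), 0.2)
        gcms.append(gcm(count_gdv(g, catalog), catalog))
    D = gcd_matrix(gcms, subject_ids=tuple(manifest.subject_id))
    res = ward_cluster(D, 2)
    ari = sklearn.adjusted_rand_score(manifest["population"], res.labels)
    assert ari >= 0.8
    # the planted cut scores better than a random balanced cut
    rng = np.random.default_rng(2)
    rand_labels = rng.permutation(np.array([1] * 10 + [2] * 10))
    _, _, rand_mean = silhouette(D, rand_labels)
    assert res.overall_mean > rand_mean
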