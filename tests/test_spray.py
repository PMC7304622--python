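"""SpRAy: descriptors, affinity graph, spectral clustering, F1, t-SNE."""

import numpy as np
import pytest
from scipy.linalg import eigh
from sklearn.base import clone

from otolens import spray
from otolens.spray import (AffinityGraph, HeatmapDescriptor, SpRAy,
                           build_affinity, clustering_f1, crop_to_contour,
                           downsample_sum, embed_tsne, knn_k,
                           make_descriptor, permutation_null_f1,
                           resize_preserving_mass, spectral_cluster)


class TestCrop:
    def test_bounding_box_shape(self):
        scores = np.arange(30 * 30, dtype=float).reshape(30, 30)
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:21, 5:16] = True
        assert crop_to_contour(scores, mask).shape == (11, 11)

    def test_full_mask_is_identity(self, rng):
        scores = rng.uniform(size=(8, 8))
        assert np.array_equal(crop_to_contour(scores, np.ones((8, 8), bool)),
                              scores)

    def test_relevance_inside_mask_conserved(self, rng):
        scores = np.zeros((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:12, 6:14] = True
        scores[mask] = rng.uniform(size=int(mask.sum()))
        assert np.isclose(crop_to_contour(scores, mask).sum(), scores.sum())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            crop_to_contour(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestDownsample:
    def test_all_ones_4x4_to_2x2_of_fours(self):
        out = downsample_sum(np.ones((4, 4)), 2)
        assert np.array_equal(out, np.full((2, 2), 4.0))

    def test_total_conserved(self, rng):
        m = rng.uniform(size=(112, 112))
        out = downsample_sum(m, 56)
        assert out.shape == (56, 56)
        assert abs(out.sum() - m.sum()) / m.sum() < 1e-6

    def test_each_cell_sums_its_block(self, rng):
        m = rng.uniform(size=(112, 112))
        out = downsample_sum(m, 56)
        assert np.isclose(out[3, 7], m[6:8, 14:16].sum())

    def test_out_size_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            downsample_sum(np.ones((10, 10)), 56)

    def test_resize_preserves_mass(self, rng):
        m = rng.uniform(size=(37, 61))
        out = resize_preserving_mass(m, (112, 112))
        assert abs(out.sum() - m.sum()) / m.sum() < 1e-9

    def test_descriptor_mass_conservation_end_to_end(self, rng):
        """crop -> resize -> sum-pool conserves total relevance when the
        relevance lies inside the mask."""
        scores = np.zeros((90, 90))
        mask = np.zeros((90, 90), dtype=bool)
        mask[10:73, 20:65] = True
        scores[mask] = rng.uniform(size=int(mask.sum()))
        d = make_descriptor(scores, mask)
        assert d.grid.shape == (56, 56)
        assert abs(d.grid.sum() - scores.sum()) / scores.sum() < 1e-6


class TestAffinity:
    def test_k_follows_natural_log_ceiling(self):
        assert knn_k(100) == 5
        assert knn_k(2) == 1

    def test_default_k_for_100_samples(self, rng):
        g = build_affinity(rng.normal(size=(100, 10)))
        assert g.k == 5

    def test_symmetric_zero_diagonal(self, rng):
        g = build_affinity(rng.normal(size=(20, 5)))
        assert np.array_equal(g.matrix, g.matrix.T)
        assert np.all(np.diag(g.matrix) == 0)

    def test_outlier_connected_via_union_symmetrization(self):
        """Three near-identical points plus one far outlier, k=1: the
        outlier keeps an edge to its nearest neighbour (brute-force
        distance table confirms which one)."""
        X = np.array([[0.0, 0], [0.01, 0], [0.02, 0], [10.0, 0]])
        g = build_affinity(X, k=1)
        d = np.linalg.norm(X[3] - X[:3], axis=1)
        nearest = int(np.argmin(d))
        assert g.matrix[3, nearest] == 1 and g.matrix[nearest, 3] == 1
        assert np.array_equal(g.matrix, g.matrix.T)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            build_affinity(np.zeros((2, 3)))


class TestSpectral:
    def test_two_disconnected_cliques_are_the_clusters(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        np.fill_diagonal(A, 0.0)
        labels = spectral_cluster(AffinityGraph(A, k=2, n=6), seed=0)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_matches_brute_force_eigendecomposition_oracle(self, rng):
        """On a tiny graph, compare against an explicit oracle: full eigh
        of the normalized Laplacian, 2 smallest eigenvectors, row
        normalization, exhaustive best 2-partition by k-means objective."""
        X = np.vstack([rng.normal(0, 0.1, (5, 3)),
                       rng.normal(5, 0.1, (5, 3))])
        g = build_affinity(X, k=2)
        labels = spectral_cluster(g, seed=0)
        # oracle
        D = g.matrix.sum(1)
        L = np.eye(g.n) - g.matrix / np.sqrt(np.outer(D, D))
        w, v = eigh(L)
        U = v[:, :2]
        U = U / np.linalg.norm(U, axis=1, keepdims=True)
        best, best_cost = None, np.inf
        for code in range(1, 2 ** (g.n - 1)):
            assign = np.array([(code >> i) & 1 for i in range(g.n)])
            cost = sum(np.sum((U[assign == c] - U[assign == c].mean(0)) ** 2)
                       for c in (0, 1) if np.any(assign == c))
            if cost < best_cost:
                best, best_cost = assign, cost
        agree = np.mean(labels == best)
        assert agree in (0.0, 1.0)  # identical up to label swap

    def test_well_separated_gaussians_fully_recovered(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 4)),
                       rng.normal(20, 1, (50, 4))])
        truth = np.repeat([0, 1], 50)
        g = build_affinity(X)
        labels = spectral_cluster(g, seed=1)
        assert clustering_f1(labels, truth) == 1.0

    def test_permutation_invariance_up_to_label_swap(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (10, 3)),
                       rng.normal(8, 0.5, (10, 3))])
        perm = rng.permutation(20)
        l1 = spectral_cluster(build_affinity(X, k=3), seed=0)
        l2 = spectral_cluster(build_affinity(X[perm], k=3), seed=0)
        back = np.empty(20, dtype=int)
        back[perm] = l2
        assert (np.array_equal(back, l1)
                or np.array_equal(back, 1 - l1))


class TestF1:
    def test_perfect_and_inverted_are_both_one(self):
        groups = np.repeat(["a", "b"], 10)
        labels = np.repeat([0, 1], 10)
        assert clustering_f1(labels, groups) == 1.0
        assert clustering_f1(1 - labels, groups) == 1.0

    def test_independent_labels_near_half(self, rng):
        """Random balanced labels vs balanced groups: expected best-match
        F1 about 0.5 (simulation at n=200)."""
        groups = np.repeat([0, 1], 100)
        f1s = [clustering_f1(rng.permutation(np.repeat([0, 1], 100)), groups)
               for _ in range(50)]
        assert abs(np.mean(f1s) - 0.5) < 0.1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustering_f1(np.zeros(3), np.zeros(4))

    def test_order_invariance(self, rng):
        labels = rng.integers(0, 2, 30)
        groups = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        assert np.isclose(clustering_f1(labels, groups),
                          clustering_f1(labels[perm], groups[perm]))


class TestTSNE:
    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(30, 6))
        g = build_affinity(X)
        a = embed_tsne(g, seed=4)
        b = embed_tsne(g, seed=4)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.coordinates.shape == (30, 2)

    def test_duplicated_descriptor_points_are_close(self, rng):
        X = rng.normal(size=(25, 6))
        X[13] = X[4]  # exact duplicate
        g = build_affinity(X)
        emb = embed_tsne(g, seed=0).coordinates
        dup = np.linalg.norm(emb[4] - emb[13])
        all_d = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        median = np.median(all_d[np.triu_indices(25, 1)])
        assert dup < median

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            embed_tsne(AffinityGraph(np.zeros((3, 3)), k=1, n=3))


class TestEstimator:
    def test_sklearn_protocol(self, rng):
        est = SpRAy(n_clusters=2, random_state=7)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        X = np.vstack([rng.normal(0, 1, (20, 5)),
                       rng.normal(10, 1, (20, 5))])
        labels = est.fit_predict(X)
        assert set(labels) == {0, 1}
        assert est.affinity_.n == 40
        assert est.score_f1(np.repeat([0, 1], 20)) == 1.0

    def test_accepts_descriptor_lists(self, rng):
        descs = []
        for i in range(12):
            grid = np.zeros((56, 56))
            region = (slice(0, 10), slice(0, 10)) if i < 6 else \
                (slice(40, 50), slice(40, 50))
            grid[region] = 1.0 + 0.01 * rng.normal(size=(10, 10))
            descs.append(HeatmapDescriptor(grid=grid, sample_id=str(i),
                                           predicted_age=2 if i < 6 else 7,
                                           variant="baseline"))
        est = SpRAy(random_state=0).fit(descs)
        assert est.score_f1([d.predicted_age for d in descs]) == 1.0


def synthetic_group_descriptors(seed, n_per_group=50):
    """Descriptors with disjoint group-specific active regions."""
    rng = np.random.default_rng(seed)
    X, groups = [], []
    for g, (rs, cs) in enumerate((((5, 20), (5, 20)), ((30, 50), (30, 50)))):
        for _ in range(n_per_group):
            grid = np.abs(rng.normal(0, 0.05, (56, 56)))
            grid[rs[0]:rs[1], cs[0]:cs[1]] += 1.0 + rng.normal(0, 0.1)
            X.append(grid.ravel())
            groups.append(g)
    return np.stack(X), np.array(groups)


def test_separable_descriptor_recovery_across_seeds():
    """Group-specific activation regions are recovered with F1 >= 0.95
    for every seed."""
    for seed in range(5):
        X, groups = synthetic_group_descriptors(seed)
        est = SpRAy(random_state=seed).fit(X)
        assert est.score_f1(groups) >= 0.95


def test_permutation_null_is_chance_level():
    X, groups = synthetic_group_descriptors(0)
    est = SpRAy(random_state=0).fit(X)
    null = permutation_null_f1(est.labels_, groups, n_permutations=100,
                               seed=1)
    assert abs(null.mean() - 0.5) < 0.1
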