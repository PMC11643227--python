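"""Distances, eigen-embedding, clustering, separability, and decoding."""

import numpy as np
import pytest
from scipy.stats import binomtest
from sklearn.metrics import adjusted_rand_score

from spikehelix.embedding import (
    DistanceMatrix,
    TrialEnsemble,
    cluster_distance_ratio,
    distance_matrix,
    eigen_projection,
    fingerprint_distance,
    kmeans_cluster,
    nearest_centroid_decode,
    spectral_cluster,
    svm_decode,
)
from spikehelix.errors import (
    DegenerateClustersError,
    InvalidDimensionError,
    ShapeMismatchError,
    StratificationError,
)
from spikehelix.geometry import helix_as_pattern
from spikehelix.synthetic import three_condition_ensemble, two_condition_ensemble
from spikehelix.transform import ms_dht

ATOL = 1e-10


def _block_distance_matrix(sizes, between=2.0):
    """Exact block structure: zero within blocks, constant between."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], 0.0, between)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d), labels


class TestFingerprintDistance:
    def test_identity(self):
        fp = ms_dht(helix_as_pattern(2, 10))
        assert fingerprint_distance(fp, fp) == 0.0

    def test_distinct_helices_distance_sqrt_two(self):
        a = ms_dht(helix_as_pattern(2, 10))
        b = ms_dht(helix_as_pattern(5, 10))
        assert abs(fingerprint_distance(a, b) - np.sqrt(2)) < ATOL

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(25):
            a, b, c = (rng.standard_normal(8) + 1j * rng.standard_normal(8) for _ in range(3))
            assert abs(fingerprint_distance(a, b) - fingerprint_distance(b, a)) < ATOL
            assert (
                fingerprint_distance(a, c)
                <= fingerprint_distance(a, b) + fingerprint_distance(b, c) + ATOL
            )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ShapeMismatchError):
            fingerprint_distance(np.zeros(3, complex), np.zeros(4, complex))


class TestDistanceMatrix:
    def test_three_pure_helices_all_sqrt_two(self):
        ens = TrialEnsemble.from_patterns(
            [helix_as_pattern(k, 12) for k in (1, 4, 9)]
        )
        d = distance_matrix(ens).values
        off = d[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off - np.sqrt(2))) < ATOL

    def test_duplicated_trial_rows_identical(self):
        fp = ms_dht(helix_as_pattern(3, 8)).mu
        other = ms_dht(helix_as_pattern(5, 8)).mu
        ens = TrialEnsemble(np.array([fp, other, fp]))
        d = distance_matrix(ens).values
        assert np.allclose(d[0], d[2])

    def test_block_structure_of_planted_ensemble(self):
        from scipy.stats import ranksums

        ens = three_condition_ensemble(seed=17)
        d = distance_matrix(ens).values
        same = ens.labels[:, None] == ens.labels[None, :]
        iu = np.triu_indices_from(d, k=1)
        within = d[iu][same[iu]]
        between = d[iu][~same[iu]]
        stat = ranksums(within, between, alternative="less")
        assert stat.pvalue < 0.01


class TestEigenProjection:
    def test_zero_matrix_projects_to_zero(self):
        d = DistanceMatrix(np.zeros((5, 5)))
        p = eigen_projection(d, 2)
        assert np.allclose(p.coords, 0.0)

    def test_block_matrix_collapses_blocks_to_points(self):
        d, labels = _block_distance_matrix([4, 4, 4])
        p = eigen_projection(d, 3)
        for c in range(3):
            block = p.coords[labels == c]
            assert np.max(np.abs(block - block[0])) < 1e-8
        centers = np.array([p.coords[labels == c][0] for c in range(3)])
        assert np.min(np.linalg.norm(centers[:, None] - centers[None, :], axis=2)[
            ~np.eye(3, dtype=bool)
        ]) > 0.1

    def test_columns_equal_eigenvalue_times_eigenvector(self, rng):
        # D @ v_i == lambda_i v_i gives an independent identity for P's columns
        a = rng.standard_normal((20, 20))
        d = np.abs(a + a.T)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d)
        p = eigen_projection(dm, 4)
        lam, vec = np.linalg.eigh(d)
        order = np.argsort(-np.abs(lam), kind="stable")
        expected = vec[:, order[:4]] * lam[order[:4]]
        # per-column sign freedom of eigenvectors
        for i in range(4):
            diff = min(
                np.max(np.abs(p.coords[:, i] - expected[:, i])),
                np.max(np.abs(p.coords[:, i] + expected[:, i])),
            )
            assert diff < 1e-8

    def test_invalid_dimension(self):
        d = DistanceMatrix(np.zeros((4, 4)))
        with pytest.raises(InvalidDimensionError):
            eigen_projection(d, 5)
        with pytest.raises(InvalidDimensionError):
            eigen_projection(d, 1)


class TestClustering:
    def test_spectral_recovers_exact_blocks(self):
        d, labels = _block_distance_matrix([5, 5, 5])
        out = spectral_cluster(d, 3, seed=0)
        assert adjusted_rand_score(labels, out) == 1.0

    def test_spectral_on_planted_ensemble(self):
        ens = three_condition_ensemble(seed=23)
        out = spectral_cluster(distance_matrix(ens), 3, seed=0)
        assert adjusted_rand_score(ens.labels, out) >= 0.9

    def test_degenerate_distances_warn(self):
        d = DistanceMatrix(np.ones((6, 6)) - np.eye(6))
        with pytest.warns(UserWarning, match="degenerate"):
            out = spectral_cluster(d, 2, seed=0)
        assert set(out) <= {0, 1}

    def test_kmeans_separated_blobs(self, rng):
        from spikehelix.embedding import Projection

        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.vstack([c + 0.1 * rng.standard_normal((10, 2)) for c in centers])
        p = Projection(coords=pts, eigenvalues=np.array([1.0, 1.0]))
        out = kmeans_cluster(p, 3, seed=0)
        truth = np.repeat(np.arange(3), 10)
        assert adjusted_rand_score(truth, out) == 1.0

    def test_kmeans_restart_stability(self, rng):
        from sklearn.cluster import KMeans

        from spikehelix.embedding import Projection

        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.vstack([c + 0.1 * rng.standard_normal((10, 2)) for c in centers])
        inertias = [
            KMeans(n_clusters=3, n_init=10, random_state=s).fit(pts).inertia_
            for s in range(5)
        ]
        assert max(inertias) - min(inertias) < 1e-8


class TestClusterDistanceRatio:
    def test_two_tight_clusters_far_apart(self, rng):
        from spikehelix.embedding import Projection

        a = rng.standard_normal((200, 2))
        a = (a - a.mean(0)) / np.linalg.norm(a - a.mean(0), axis=1).mean()
        pts = np.vstack([a, a + [10.0, 0.0]])
        p = Projection(coords=pts, eigenvalues=np.array([1.0, 1.0]))
        labels = np.repeat([0, 1], 200)
        ratio = cluster_distance_ratio(p, labels)
        assert ratio == pytest.approx(10.0, rel=0.05)

    def test_coincident_points_raise(self):
        from spikehelix.embedding import Projection

        p = Projection(coords=np.zeros((6, 2)), eigenvalues=np.array([0.0]))
        with pytest.raises(DegenerateClustersError):
            cluster_distance_ratio(p, np.repeat([0, 1], 3))

    def test_identical_points_per_cluster_give_inf(self):
        from spikehelix.embedding import Projection

        pts = np.repeat([[0.0, 0.0], [5.0, 0.0]], 3, axis=0)
        p = Projection(coords=pts, eigenvalues=np.array([1.0]))
        with pytest.warns(UserWarning, match="inf"):
            assert cluster_distance_ratio(p, np.repeat([0, 1], 3)) == np.inf

    def test_overlapping_clouds_below_one(self, rng):
        from spikehelix.embedding import Projection

        pts = rng.standard_normal((100, 2))
        p = Projection(coords=pts, eigenvalues=np.array([1.0]))
        labels = rng.integers(0, 2, 100)
        assert cluster_distance_ratio(p, labels) < 1.0


class TestNearestCentroidDecode:
    def test_separated_ensemble_decodes_perfectly(self):
        ens = three_condition_ensemble(fraction=1.0, seed=4)
        d = distance_matrix(ens)
        p = eigen_projection(d, 3)
        res = nearest_centroid_decode(p, ens.labels, 10, seed=0)
        assert res.accuracy == 1.0

    def test_shuffled_labels_at_chance(self, rng):
        ens = three_condition_ensemble(seed=6)
        d = distance_matrix(ens)
        p = eigen_projection(d, 3)
        shuffled = rng.permutation(ens.labels)
        res = nearest_centroid_decode(p, shuffled, 5, seed=0)
        ci = binomtest(round(res.accuracy * 75), 75, 1 / 3).proportion_ci(0.999)
        assert ci.low <= 1 / 3 <= ci.high

    def test_refit_per_fold_mode_runs(self):
        ens = three_condition_ensemble(fraction=1.0, seed=4)
        d = distance_matrix(ens)
        p = eigen_projection(d, 3)
        res = nearest_centroid_decode(p, ens.labels, 5, seed=0, refit_from=d)
        assert res.accuracy >= 0.9

    def test_stratification_guard(self):
        ens = three_condition_ensemble(seed=4)
        d = distance_matrix(ens)
        p = eigen_projection(d, 3)
        with pytest.raises(StratificationError):
            nearest_centroid_decode(p, ens.labels, 26, seed=0)


class TestSvmDecode:
    def test_noiseless_planted_helices_decode_perfectly(self):
        ens = two_condition_ensemble(fraction=1.0, background_counts=0, seed=1)
        res = svm_decode(ens, [2, 8], 10, seed=0)
        assert res.accuracy == 1.0

    def test_label_shuffle_at_chance(self, rng):
        ens = two_condition_ensemble(seed=3)
        shuffled = TrialEnsemble(ens.fingerprints, labels=rng.permutation(ens.labels))
        res = svm_decode(shuffled, [2, 8], 10, seed=0)
        ci = binomtest(round(res.accuracy * 50), 50, 0.5).proportion_ci(0.999)
        assert ci.low <= 0.5 <= ci.high

    def test_single_class_rejected(self):
        ens = two_condition_ensemble(seed=3)
        mono = TrialEnsemble(ens.fingerprints, labels=np.zeros(ens.n_trials))
        with pytest.raises(ValueError):
            svm_decode(mono, [2, 8], 10, seed=0)

    def test_empty_subset_rejected(self):
        ens = two_condition_ensemble(seed=3)
        with pytest.raises(ValueError):
            svm_decode(ens, [], 10, seed=0)


class TestRelabelingEndToEnd:
    def test_common_relabeling_leaves_distance_matrix_unchanged(self, rng):
        from spikehelix.synthetic import three_condition_ensemble
        from spikehelix.transform import relabel_pattern

        ens, patterns = three_condition_ensemble(
            n_neurons=30, n_trials=15, seed=8, return_patterns=True
        )
        perm = rng.permutation(np.arange(1, 31))
        relabeled = TrialEnsemble.from_patterns(
            [relabel_pattern(p, perm) for p in patterns], labels=ens.labels
        )
        d0 = distance_matrix(ens).values
        d1 = distance_matrix(relabeled).values
        assert np.max(np.abs(d0 - d1)) < ATOL
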