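"""Feature extraction, affinity propagation, PCA variance accounting."""

import numpy as np
import pandas as pd
import pytest

from chrysid.features import (APConfig, FeatureMatrix, adjusted_rand_index,
                              affinity_propagation, cultivar_mean_features,
                              extract_features, label_projection_report, pca,
                              similarity_matrix, variance_accounting)


@pytest.fixture(scope="module")
def net():
    from chrysid.nn import BackboneConfig, HeadConfig, build_network, he_initialize
    return he_initialize(build_network(BackboneConfig.preset("tiny"),
                                       HeadConfig(4, 2, 2)), 2)


class TestFeatureExtraction:

    def test_shape_is_batch_by_feature_dim(self, net, rng):
        X = rng.random((6, 3, 48, 48), dtype=np.float32)
        fm = extract_features(net, X)
        assert fm.X.shape == (6, 16)

    def test_duplicate_images_give_identical_rows(self, net, rng):
        x = rng.random((1, 3, 48, 48), dtype=np.float32)
        fm = extract_features(net, np.concatenate([x, x]))
        np.testing.assert_array_equal(fm.X[0], fm.X[1])

    def test_paper_scale_backbone_yields_512_dims(self):
        from chrysid.nn import BackboneConfig
        assert BackboneConfig.preset("paper18").feature_dim == 512

    def test_csv_roundtrip(self, tmp_path, rng):
        fm = FeatureMatrix(rng.random((4, 3)), ["a", "b", "c", "d"],
                           annotations=pd.DataFrame({"petal_type":
                                                     ["flat"] * 4}))
        fm.to_csv(tmp_path / "f.csv")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.X, fm.X)
        assert back.row_labels == fm.row_labels
        assert back.annotations["petal_type"].tolist() == ["flat"] * 4


class TestCultivarPooling:
    def _manifest(self, ids):
        from chrysid.manifest import Manifest
        df = pd.DataFrame({"path": [f"/x/{i}.png" for i in range(len(ids))],
                           "cultivar_id": ids, "petal_type": "flat",
                           "flower_type": "lotus-like", "year": "2018",
                           "view": "top"})
        return Manifest(df)

    def test_one_image_per_cultivar_is_identity(self, rng):
        X = rng.random((3, 5))
        fm = FeatureMatrix(X, ["r0", "r1", "r2"])
        m = self._manifest(["a", "b", "c"])
        pooled = cultivar_mean_features(fm, m)
        np.testing.assert_allclose(np.sort(pooled.X, axis=0), np.sort(X, axis=0))

    def test_mean_of_identical_rows_equals_row(self, rng):
        row = rng.random(4)
        fm = FeatureMatrix(np.stack([row, row]), ["r0", "r1"])
        pooled = cultivar_mean_features(fm, self._manifest(["a", "a"]))
        np.testing.assert_allclose(pooled.X[0], row)

    def test_row_count_equals_cultivar_count(self, rng):
        ids = [f"cv_{i % 7}" for i in range(21)]
        fm = FeatureMatrix(rng.random((21, 6)), [str(i) for i in range(21)])
        pooled = cultivar_mean_features(fm, self._manifest(ids))
        assert pooled.X.shape == (7, 6)

    def test_mismatched_rows_rejected(self, rng):
        fm = FeatureMatrix(rng.random((2, 3)), ["a", "b"])
        with pytest.raises(ValueError):
            cultivar_mean_features(fm, self._manifest(["a", "b", "c"]))


def _blobs(rng, centers, n=12, noise=0.1, d=5):
    return np.concatenate([rng.normal(c, noise, (n, d)) for c in centers])


class TestAffinityPropagation:
    def test_single_point_is_its_own_exemplar(self):
        res = affinity_propagation(np.zeros((1, 3)), APConfig())
        assert res.n_clusters == 1 and res.exemplar_of[0] == 0

    @pytest.mark.parametrize("centers,noise", [((0.0, 4.0, 8.0), 0.1),
                                               ((0.0, 3.0), 0.3),
                                               ((0.0, 2.0, 4.0, 6.0), 0.15)])
    def test_matches_reference_implementation_on_blobs(self, rng, centers, noise):
        """Partition equivalence with scikit-learn on <= 50-point instances,
        matched similarity (negative squared distance), median preference,
        damping 0.9, 1000 iterations, stability window 100."""
        from sklearn.cluster import AffinityPropagation
        X = _blobs(rng, centers, n=min(12, 50 // len(centers)), noise=noise)
        S = similarity_matrix(X)
        pref = float(np.median(S[~np.eye(len(X), dtype=bool)]))
        mine = affinity_propagation(X, APConfig(preference=pref))
        ref = AffinityPropagation(damping=0.9, max_iter=1000, convergence_iter=100,
                                  preference=pref, random_state=0).fit(X)
        assert mine.n_clusters == len(centers)
        assert adjusted_rand_index(mine.labels, ref.labels_) == 1.0

    def test_high_preference_makes_every_point_an_exemplar(self, rng):
        X = rng.normal(0, 1, (20, 3))
        res = affinity_propagation(X, APConfig(preference=1000.0))
        assert res.n_clusters == 20
        np.testing.assert_array_equal(res.exemplar_of, np.arange(20))

    def test_exemplars_are_their_own_exemplars(self, rng):
        X = _blobs(rng, (0.0, 5.0), n=10, noise=0.2)
        res = affinity_propagation(X, APConfig())
        for e in res.exemplars:
            assert res.exemplar_of[e] == e

    def test_partition_stable_under_row_permutation(self, rng):
        X = _blobs(rng, (0.0, 4.0, 8.0), n=8, noise=0.1)
        perm = rng.permutation(len(X))
        a = affinity_propagation(X, APConfig())
        b = affinity_propagation(X[perm], APConfig())
        assert adjusted_rand_index(a.labels[perm], b.labels) == 1.0

    def test_non_finite_features_rejected(self):
        X = np.zeros((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            affinity_propagation(X, APConfig())

    def test_invalid_damping_rejected(self):
        with pytest.raises(ValueError):
            APConfig(damping=0.4)


class TestAdjustedRand:
    def test_matches_sklearn(self, rng):
        from sklearn.metrics import adjusted_rand_score
        for _ in range(5):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            assert adjusted_rand_index(a, b) == \
                   pytest.approx(adjusted_rand_score(a, b))

    def test_identical_partitions_score_one(self, rng):
        a = rng.integers(0, 4, 30)
        assert adjusted_rand_index(a, a) == 1.0


class TestPCA:
    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(0, 1, (40, 6)) @ rng.normal(0, 1, (6, 6))
        res = pca(X, standardize=False)
        expected = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-10)

    def test_known_two_by_two_covariance(self, rng):
        # X with sample covariance exactly [[2,1],[1,2]]: eigenvalues 3 and 1
        base = rng.normal(0, 1, (500, 2))
        base -= base.mean(axis=0)
        C = np.linalg.cholesky(np.cov(base.T))
        white = base @ np.linalg.inv(C).T       # exactly identity covariance
        A = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        X = white @ A.T
        res = pca(X, standardize=False)
        np.testing.assert_allclose(res.eigenvalues, [3.0, 1.0], atol=1e-8)

    def test_two_distinct_points_are_rank_one(self):
        res = pca(np.array([[0.0, 0.0], [1.0, 2.0]]), standardize=False)
        assert res.importance[0] == pytest.approx(100.0)
        assert np.sum(res.eigenvalues > 1e-12) == 1

    def test_standardized_importance_sums_to_100(self, rng):
        X = rng.normal(0, [1, 5, 0.1, 2], (30, 4))
        res = pca(X, standardize=True)
        assert res.total_variance == 4.0
        assert res.importance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(res.cumulative) >= -1e-12).all()

    def test_reconstruction_from_all_components(self, rng):
        X = rng.normal(0, 1, (20, 5))
        res = pca(X, standardize=True)
        Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        np.testing.assert_allclose(res.components.T @ res.components,
                                   np.eye(res.components.shape[1]), atol=1e-10)
        recon = (Xc @ res.components.T) @ res.components
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = rng.normal(0, 1, (15, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca(X, standardize=True)
        assert res.total_variance == 2.0
        assert res.dropped_columns == [1]

    def test_variance_accounting_reproduces_published_style_table(self):
        # eigenvalue 57.437 of a 512-dim correlation PCA -> importance 11.218%
        imp, cum = variance_accounting([57.437, 49.524], 512.0)
        assert round(imp[0], 3) == 11.218
        assert round(imp[1], 3) == 9.673
        assert round(cum[1], 3) == 20.891
        imp38, _ = variance_accounting([1.707], 512.0)
        assert round(imp38[0], 3) == 0.333


class TestLabelProjection:
    def test_single_group_centroid_is_global_mean(self, rng):
        X = rng.normal(0, 1, (10, 4))
        res = pca(X, standardize=False)
        rep = label_projection_report(res, ["g"] * 10)
        np.testing.assert_allclose(rep.loc["g", ["pc1", "pc2"]].to_numpy(float),
                                   res.scores.mean(axis=0), atol=1e-12)

    def test_group_sizes_sum_to_n(self, rng):
        X = rng.normal(0, 1, (12, 4))
        res = pca(X, standardize=False)
        rep = label_projection_report(res, ["a", "b", "c"] * 4)
        assert rep["n"].sum() == 12

    def test_distant_groups_have_separated_centroids(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, (10, 4)),
                            rng.normal(5, 0.1, (10, 4))])
        res = pca(X, standardize=False)
        rep = label_projection_report(res, ["a"] * 10 + ["b"] * 10)
        sep = np.linalg.norm(rep.loc["a", ["pc1", "pc2"]].to_numpy(float)
                             - rep.loc["b", ["pc1", "pc2"]].to_numpy(float))
        assert sep > rep["dispersion"].max() * 2

    def test_missing_annotation_rejected(self, rng):
        res = pca(rng.normal(0, 1, (4, 3)), standardize=False)
        with pytest.raises(ValueError):
            label_projection_report(res, ["a", None, "b", "b"])
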