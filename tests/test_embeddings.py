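"""Filter-bank embeddings, pooling and PCA reduction."""

import numpy as np
import pytest

from drfusion.embeddings import (ConvSpec, PCAReducer, PoolSpec, conv2d,
                                 filterbank_embed, filterbank_weights,
                                 pca_fit, pca_reduce, pool)
from drfusion.image import GrayImage

from _oracles import (conv2d_bruteforce, pca_eigh_bruteforce, pool_bruteforce)


class TestPool:
    @pytest.mark.parametrize("mode", ["average", "max"])
    def test_constant_image(self, mode):
        out = pool(GrayImage(np.full((8, 8), 0.3)), PoolSpec(mode=mode))
        np.testing.assert_allclose(out.pixels, 0.3)

    def test_2x2_window_definitions(self):
        block = GrayImage(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(
            pool(block, PoolSpec(mode="max", window=2)).pixels, [[4.0]])
        np.testing.assert_allclose(
            pool(block, PoolSpec(mode="average", window=2)).pixels, [[2.5]])

    @pytest.mark.parametrize("mode", ["average", "max"])
    def test_strided_matches_double_loop_oracle(self, rng, mode):
        img = rng.uniform(0, 1, (9, 9))
        ours = pool(GrayImage(img), PoolSpec(mode=mode, window=3, stride=2))
        np.testing.assert_allclose(ours.pixels,
                                   pool_bruteforce(img, 3, 2, mode), atol=1e-12)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError, match="window"):
            pool(GrayImage(np.zeros((4, 4))), PoolSpec(window=5))


class TestConv:
    def test_allones_3x3_matches_unrolled_oracle(self):
        img = np.arange(36, dtype=float).reshape(6, 6) / 36.0
        w = np.ones((3, 3)) / 9.0
        np.testing.assert_allclose(conv2d(img, w),
                                   conv2d_bruteforce(img, w), atol=1e-12)

    def test_random_kernel_matches_oracle(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        w = rng.uniform(-1, 1, (5, 5))
        np.testing.assert_allclose(conv2d(img, w),
                                   conv2d_bruteforce(img, w), atol=1e-12)


class TestFilterBankEmbed:
    def test_zero_image_gives_zero_embedding(self):
        e = filterbank_embed(GrayImage(np.zeros((32, 32))),
                             ConvSpec(n_filters=8), out_dim=64)
        assert not e.values.any()

    def test_deterministic_given_seed(self, random_gray):
        a = filterbank_embed(GrayImage(random_gray), ConvSpec(n_filters=8),
                             out_dim=64)
        b = filterbank_embed(GrayImage(random_gray), ConvSpec(n_filters=8),
                             out_dim=64)
        assert a.values.tobytes() == b.values.tobytes()

    def test_tiling_to_out_dim(self, random_gray):
        e = filterbank_embed(GrayImage(random_gray), ConvSpec(n_filters=8),
                             out_dim=20)
        assert len(e) == 20
        np.testing.assert_array_equal(e.values[8:16], e.values[:8])

    def test_out_dim_below_n_filters_rejected(self, random_gray):
        with pytest.raises(ValueError, match="out_dim"):
            filterbank_embed(GrayImage(random_gray), ConvSpec(n_filters=16),
                             out_dim=8)

    def test_lipschitz_bound_single_pixel(self, rng):
        conv = ConvSpec(n_filters=4, seed=99)
        img = rng.uniform(0.2, 0.8, (24, 24))
        eps = 0.01
        perturbed = img.copy()
        perturbed[11, 11] += eps
        a = filterbank_embed(GrayImage(img), conv, out_dim=4).values
        b = filterbank_embed(GrayImage(perturbed), conv, out_dim=4).values
        w = filterbank_weights(conv)
        C = (np.abs(w[0]).sum(axis=(1, 2)).max()
             * np.abs(w[1]).sum(axis=(1, 2)).max())
        assert np.max(np.abs(a - b)) <= C * eps + 1e-12


class TestPCA:
    def test_line_in_3d_explains_all_variance(self):
        t = np.linspace(0, 1, 20)
        X = np.outer(t, [1.0, 2.0, -1.0])
        model = pca_fit(X, 1)
        total = X.var(axis=0, ddof=1).sum()
        assert model.explained_variance[0] == pytest.approx(total)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(30, 5))
        model = pca_fit(X, 5)
        Z = pca_reduce(X, model)
        back = Z @ model.component_matrix + model.mean_vector
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_eigenvalues_match_covariance_oracle(self, rng):
        X = rng.normal(size=(50, 10))
        model = pca_fit(X, 10)
        vals, vecs = pca_eigh_bruteforce(X, 10)
        np.testing.assert_allclose(model.explained_variance, vals, atol=1e-8)
        # components agree up to sign
        dots = np.abs(np.sum(model.component_matrix * vecs, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_components_orthonormal_and_ordered(self, rng):
        X = rng.normal(size=(40, 8))
        model = pca_fit(X, 6)
        gram = model.component_matrix @ model.component_matrix.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-10)

    def test_projection_variances_non_increasing(self, rng):
        X = rng.normal(size=(60, 12)) * np.linspace(3, 0.5, 12)
        Z = pca_reduce(X, pca_fit(X, 8))
        v = Z.var(axis=0, ddof=1)
        assert np.all(np.diff(v) <= 1e-10)

    def test_k_too_large_reports_max(self):
        X = np.random.default_rng(0).normal(size=(5, 10))
        with pytest.raises(ValueError, match="maximum feasible k is 4"):
            pca_fit(X, 7)

    def test_dimension_mismatch_rejected(self, rng):
        model = pca_fit(rng.normal(size=(10, 4)), 2)
        with pytest.raises(ValueError, match="columns"):
            pca_reduce(rng.normal(size=(3, 5)), model)

    def test_total_variance_preserved_at_full_rank(self, rng):
        X = rng.normal(size=(25, 6))
        model = pca_fit(X, 6)
        Z = pca_reduce(X, model)
        assert Z.var(axis=0, ddof=1).sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum(), rel=1e-6)

    def test_reducer_cap_rule(self, rng):
        X = rng.normal(size=(500, 700))
        reducer = PCAReducer(k=1024).fit(X)
        assert reducer.k_ == min(1024, 499, 700) == 499
        assert reducer.transform(X).shape == (500, 499)

    def test_model_roundtrip_through_files(self, rng, tmp_path):
        from drfusion.embeddings import PCAModel

        model = pca_fit(rng.normal(size=(12, 5)), 3)
        model.to_files(tmp_path / "pca")
        back = PCAModel.from_files(tmp_path / "pca")
        np.testing.assert_allclose(back.component_matrix,
                                   model.component_matrix, atol=1e-12)
        assert back.k == 3
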