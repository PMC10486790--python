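"""Classifier paths: fusion, SVM, FFNN and the prediction contract."""

import numpy as np
import pytest

from drfusion.models import (FusionFFNNClassifier, HybridSVMClassifier,
                             SVMSpec, ffnn_train, fuse_features, predict,
                             svm_train)


def gaussian_blobs(rng, n_classes=5, n_per_class=40, dim=20, sep=8.0):
    """Well-separated seeded blobs: separable by construction."""
    centers = rng.normal(scale=sep, size=(n_classes, dim))
    X = np.vstack([centers[c] + rng.normal(size=(n_per_class, dim))
                   for c in range(n_classes)])
    y = np.repeat(np.arange(n_classes), n_per_class)
    return X, y


class TestFuseFeatures:
    def test_full_scale_width(self, rng):
        fused = fuse_features(rng.normal(size=(3, 1024)),
                              rng.normal(size=(3, 232)))
        assert fused.shape == (3, 1256)

    def test_block_recovery(self, rng):
        deep = rng.normal(size=(4, 100))
        hand = rng.normal(size=(4, 232))
        fused = fuse_features(deep, hand)
        np.testing.assert_array_equal(fused[:, :100], deep)
        np.testing.assert_array_equal(fused[:, 100:], hand)

    def test_zero_inputs_stay_zero(self):
        fused = fuse_features(np.zeros((2, 1024)), np.zeros((2, 232)))
        assert not fused.any()

    def test_wrong_handcrafted_width_rejected(self, rng):
        with pytest.raises(ValueError, match="handcrafted"):
            fuse_features(rng.normal(size=(2, 1024)),
                          rng.normal(size=(2, 231)))


class TestSVM:
    def test_separable_blobs_train_accuracy_100(self, rng):
        X, y = gaussian_blobs(rng, n_classes=2, dim=5)
        clf = svm_train(X, y)
        assert clf.score(X, y) == 1.0

    def test_contradictory_labels_bounded_accuracy(self, rng):
        X = np.tile(rng.normal(size=(10, 4)), (2, 1))
        y = np.array([0] * 10 + [1] * 10)  # identical points, opposite labels
        clf = svm_train(X, y)
        assert clf.score(X, y) <= 0.5

    def test_xor_rbf_separates_linear_does_not(self, rng):
        corners = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        X = np.repeat(corners, 20, axis=0) + rng.normal(scale=0.05,
                                                        size=(80, 2))
        y = np.array([0] * 40 + [1] * 40)
        rbf = svm_train(X, y, SVMSpec(kernel="rbf"))
        linear = svm_train(X, y, SVMSpec(kernel="linear"))
        assert rbf.score(X, y) == 1.0
        assert linear.score(X, y) <= 0.75

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            svm_train(rng.normal(size=(10, 3)), np.zeros(10))

    def test_probability_rows_sum_to_one(self, rng):
        X, y = gaussian_blobs(rng, n_classes=3, dim=6)
        clf = svm_train(X, y)
        probs = clf.predict_proba(X[:7])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)


class TestFFNN:
    def test_probability_rows_sum_to_one(self, rng):
        X, y = gaussian_blobs(rng, n_classes=5, dim=10, n_per_class=20)
        clf = ffnn_train(X, y)
        probs = clf.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_blobs_high_dim_training_accuracy(self, rng):
        X, y = gaussian_blobs(rng, n_classes=5, n_per_class=50, dim=1256,
                              sep=4.0)
        clf = ffnn_train(X, y)
        assert clf.score(X, y) >= 0.99

    def test_permuted_labels_give_chance_level_validation(self, rng):
        X, y = gaussian_blobs(rng, n_classes=5, n_per_class=100, dim=10)
        y_perm = rng.permutation(y)
        clf = FusionFFNNClassifier(random_state=0).fit(X, y_perm)
        X_fresh, y_fresh = gaussian_blobs(np.random.default_rng(77),
                                          n_classes=5, n_per_class=100, dim=10)
        acc = clf.score(X_fresh, rng.permutation(y_fresh))
        assert abs(acc - 0.2) < 0.05

    def test_loss_decreases_on_separable_data(self, rng):
        X, y = gaussian_blobs(rng, n_classes=3, n_per_class=60, dim=8)
        clf = ffnn_train(X, y)
        losses = clf.loss_curve_
        assert losses[min(10, len(losses) - 1)] < losses[0]

    def test_non_finite_features_rejected(self, rng):
        X, y = gaussian_blobs(rng, n_classes=2, dim=4)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ffnn_train(X, y)


class TestPredict:
    def test_training_data_perfect_on_separable_blobs(self, rng):
        X, y = gaussian_blobs(rng, n_classes=4, dim=8)
        clf = svm_train(X, y)
        labels, probs = predict(clf, X)
        np.testing.assert_array_equal(labels, y)
        assert probs.shape == (len(y), 4)

    def test_empty_input_empty_output(self, rng):
        X, y = gaussian_blobs(rng, n_classes=2, dim=4)
        clf = svm_train(X, y)
        labels, probs = predict(clf, np.empty((0, 4)))
        assert labels.size == 0 and probs.shape[0] == 0

    def test_deterministic_repeated_calls(self, rng):
        X, y = gaussian_blobs(rng, n_classes=3, dim=6)
        clf = ffnn_train(X, y)
        a, pa = predict(clf, X)
        b, pb = predict(clf, X)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(pa, pb)

    def test_width_mismatch_rejected(self, rng):
        X, y = gaussian_blobs(rng, n_classes=2, dim=4)
        clf = svm_train(X, y)
        with pytest.raises(ValueError, match="features"):
            clf.predict(rng.normal(size=(3, 5)))


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        clf = HybridSVMClassifier(C=2.0)
        params = clf.get_params()
        assert params["C"] == 2.0
        clf.set_params(C=0.5, kernel="linear")
        assert clf.C == 0.5 and clf.kernel == "linear"

    def test_identical_seed_identical_predictions(self, rng):
        X, y = gaussian_blobs(rng, n_classes=3, dim=10, sep=2.0)
        a = FusionFFNNClassifier(random_state=4).fit(X, y).predict(X)
        b = FusionFFNNClassifier(random_state=4).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)


def test_fusion_no_worse_than_single_paths(small_corpus):
    """Fused deep+handcrafted features should not lose information
    relative to either block alone (macro accuracy within 0.05)."""
    from drfusion.embeddings import FilterBankEmbedder, PCAReducer
    from drfusion.evaluation import evaluate
    from drfusion.handcrafted import HandcraftedExtractor
    from drfusion.preprocess import FundusEnhancer

    images, _ = small_corpus
    y = np.array([img.label for img in images])
    rng = np.random.default_rng(0)
    order = rng.permutation(len(images))
    train, test = order[:70], order[70:]

    enhanced = FundusEnhancer().transform(images)
    hand = HandcraftedExtractor().transform(images)
    deep_raw = FilterBankEmbedder(n_filters=32, out_dim=128).transform(enhanced)
    pca = PCAReducer(k=64).fit(deep_raw[train])
    deep = pca.transform(deep_raw)

    accs = {}
    for name, X in (("hand", hand), ("deep", deep),
                    ("fused", np.hstack([deep, hand]))):
        clf = FusionFFNNClassifier(random_state=1).fit(X[train], y[train])
        labels, probs = predict(clf, X[test])
        accs[name] = evaluate(y[test], labels, probs).accuracy
    assert accs["fused"] >= max(accs["hand"], accs["deep"]) - 5.0
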