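"""Classifier paths: hybrid (embedding -> PCA -> SVM) and fusion (FFNN).

Both classifiers are scikit-learn style estimators that z-score features
with training-set statistics before fitting:

* :class:`HybridSVMClassifier` — a max-margin classifier (RBF kernel by
  default) over PCA-reduced embeddings.  Prediction is the argmax of the
  one-vs-rest decision values, with ties broken toward the lower class
  index; ``predict_proba`` returns a softmax of those values (scores, not
  calibrated probabilities).
* :class:`FusionFFNNClassifier` — a single-hidden-layer feed-forward network
  (default 15 logistic units, softmax output, cross-entropy loss) trained by
  seeded mini-batch gradient descent with early stopping on an internal
  held-out fold.

Feature fusion concatenates the deep block (1024 after PCA at full scale)
with the 232 handcrafted features into a 1256-wide vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .handcrafted import HANDCRAFTED_DIM, HANDCRAFTED_LAYOUT, FeatureVector

DEEP_DIM = 1024
FUSED_DIM = DEEP_DIM + HANDCRAFTED_DIM  # 1256
FUSED_LAYOUT = (("deep", DEEP_DIM),) + HANDCRAFTED_LAYOUT


@dataclass
class FFNNSpec:
    input_dim: int = FUSED_DIM
    hidden_units: int = 15
    output_dim: int = 5
    max_epochs: int = 500
    learning_rate: float = 1e-3
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_units, self.output_dim) <= 0:
            raise ValueError("dimensions must be > 0")


@dataclass
class SVMSpec:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")


def fuse_features(deep: np.ndarray, hand: np.ndarray) -> np.ndarray:
    """Concatenate deep || handcrafted row-wise; widths must match the layout.

    The deep block may be narrower than 1024 when PCA was capped by a small
    corpus; the handcrafted block must be exactly 232.  Standardization is
    the classifiers' job (fitted on training data), so fusion itself is a
    plain concatenation and slicing the output recovers the inputs exactly.
    """
    deep = np.atleast_2d(np.asarray(deep, dtype=float))
    hand = np.atleast_2d(np.asarray(hand, dtype=float))
    if deep.shape[0] != hand.shape[0]:
        raise ValueError("deep and handcrafted row counts differ")
    if hand.shape[1] != HANDCRAFTED_DIM:
        raise ValueError(f"handcrafted block must be {HANDCRAFTED_DIM} wide, "
                         f"got {hand.shape[1]}")
    if deep.shape[1] > DEEP_DIM:
        raise ValueError(f"deep block must be <= {DEEP_DIM} wide, "
                         f"got {deep.shape[1]}")
    return np.hstack([deep, hand])


def fuse_vectors(deep: FeatureVector, hand: FeatureVector) -> FeatureVector:
    """Single-vector fusion preserving the named block layout."""
    fused = fuse_features(deep.values[None, :], hand.values[None, :])[0]
    layout = (("deep", len(deep)),) + hand.layout
    return FeatureVector(fused, layout)


def _validate_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train")
    return X, y


class _ScaledClassifierBase:
    """Shared plumbing: z-scoring, argmax prediction with low-index ties."""

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise RuntimeError("classifier is not fitted")

    def _transform(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, "
                             f"got {X.shape[1] if X.ndim == 2 else 'non-2D'}")
        return self.scaler_.transform(X)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        scores = self.predict_proba(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self


class HybridSVMClassifier(_ScaledClassifierBase):
    """Max-margin classifier over standardized features (SVM path)."""

    _param_names = ("kernel", "C", "gamma", "random_state")
    _estimator_type = "classifier"

    def __init__(self, kernel: str = "rbf", C: float = 1.0,
                 gamma: str | float = "scale", random_state: int = 0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        SVMSpec(kernel=self.kernel, C=self.C, gamma=self.gamma)
        X, y = _validate_Xy(X, y)
        self.scaler_ = StandardScaler().fit(X)
        self.svc_ = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                        decision_function_shape="ovr",
                        random_state=self.random_state)
        self.svc_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        scores = self.svc_.decision_function(self._transform(X))
        if scores.ndim == 1:  # binary: expand to two columns
            scores = np.column_stack([-scores, scores])
        return scores

    def predict_proba(self, X) -> np.ndarray:
        """Softmax of decision values: a ranking score, not calibrated."""
        scores = self.decision_function(X)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)


class FusionFFNNClassifier(_ScaledClassifierBase):
    """One-hidden-layer feed-forward network over standardized features."""

    _param_names = ("hidden_units", "max_epochs", "learning_rate", "patience",
                    "random_state")
    _estimator_type = "classifier"

    def __init__(self, hidden_units: int = 15, max_epochs: int = 500,
                 learning_rate: float = 1e-3, patience: int = 20,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_Xy(X, y)
        FFNNSpec(input_dim=X.shape[1], hidden_units=self.hidden_units,
                 output_dim=int(np.unique(y).size), max_epochs=self.max_epochs,
                 learning_rate=self.learning_rate, patience=self.patience,
                 seed=self.random_state)
        self.scaler_ = StandardScaler().fit(X)
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,), activation="logistic",
            solver="adam", learning_rate_init=self.learning_rate,
            max_iter=self.max_epochs, early_stopping=True,
            validation_fraction=0.1, n_iter_no_change=self.patience,
            random_state=self.random_state)
        self.mlp_.fit(self.scaler_.transform(X), y)
        if not np.all(np.isfinite(self.mlp_.loss_curve_)):
            raise RuntimeError("FFNN training diverged (non-finite loss)")
        self.classes_ = self.mlp_.classes_
        self.n_features_in_ = X.shape[1]
        self.loss_curve_ = list(self.mlp_.loss_curve_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.mlp_.predict_proba(self._transform(X))


# thin functional wrappers -------------------------------------------------

def svm_train(X, y, spec: SVMSpec | None = None) -> HybridSVMClassifier:
    spec = spec or SVMSpec()
    return HybridSVMClassifier(kernel=spec.kernel, C=spec.C, gamma=spec.gamma,
                               random_state=spec.seed).fit(X, y)


def ffnn_train(X, y, spec: FFNNSpec | None = None) -> FusionFFNNClassifier:
    spec = spec or FFNNSpec()
    return FusionFFNNClassifier(hidden_units=spec.hidden_units,
                                max_epochs=spec.max_epochs,
                                learning_rate=spec.learning_rate,
                                patience=spec.patience,
                                random_state=spec.seed).fit(X, y)


def predict(classifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and the probability (or softmax-score) matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        n_cls = len(getattr(classifier, "classes_", [])) or 5
        return np.empty(0, dtype=int), np.empty((0, n_cls))
    probs = classifier.predict_proba(X)
    labels = classifier.classes_[np.argmax(probs, axis=1)]
    return labels, probs
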