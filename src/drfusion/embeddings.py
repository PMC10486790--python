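"""Deep-style embeddings: seeded random filter bank and PCA reduction.

The embedding stage mimics the shape of a small convolutional feature
extractor without any training: two rounds of (seeded random convolution ->
rectification -> pooling), followed by global average pooling per map, tiled
to a fixed output width (default 4096).  The filter weights are drawn once
from ``uniform(-1, 1) / kernel**2`` with a fixed seed, so embeddings are a
deterministic, Lipschitz function of the input.  An adapter for a genuinely
pretrained backbone can replace this stage as long as it honors the same
output-width contract.

PCA then reduces the embedding matrix to at most 1024 components (capped at
``min(k, n_samples - 1, n_features)`` so small corpora remain valid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .handcrafted import FeatureVector
from .image import GrayImage, as_pixels

DEFAULT_EMBED_DIM = 4096
DEFAULT_PCA_K = 1024
DEFAULT_SEED = 1742


@dataclass
class ConvSpec:
    n_filters: int = 64
    kernel: int = 5
    stride: int = 1
    padding: str = "zero"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.padding != "zero":
            raise ValueError("only zero padding is supported")


@dataclass
class PoolSpec:
    mode: str = "average"
    window: int = 2
    stride: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("average", "max"):
            raise ValueError("mode must be 'average' or 'max'")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class PCAModel:
    """Fitted PCA: orthonormal components with non-increasing variance."""

    mean_vector: np.ndarray
    component_matrix: np.ndarray  # (k, d)
    explained_variance: np.ndarray
    k: int

    def to_files(self, stem: str | Path) -> None:
        stem = Path(stem)
        np.savetxt(stem.with_suffix(".components.csv"), self.component_matrix,
                   delimiter=",")
        meta = {"k": self.k, "mean": self.mean_vector.tolist(),
                "explained_variance": self.explained_variance.tolist()}
        stem.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def from_files(cls, stem: str | Path) -> "PCAModel":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        comps = np.loadtxt(stem.with_suffix(".components.csv"), delimiter=",")
        comps = np.atleast_2d(comps)
        return cls(np.asarray(meta["mean"]), comps,
                   np.asarray(meta["explained_variance"]), meta["k"])


def conv2d(pixels: np.ndarray, weights: np.ndarray, stride: int = 1) -> np.ndarray:
    """Cross-correlation with zero padding ('same' at stride 1)."""
    out = ndimage.correlate(pixels, weights, mode="constant", cval=0.0)
    return out[::stride, ::stride]


def pool(block, spec: PoolSpec | None = None) -> GrayImage:
    """Window pooling; output side = floor((side - window)/stride) + 1."""
    spec = spec or PoolSpec()
    pixels = as_pixels(block)
    if spec.window > min(pixels.shape):
        raise ValueError("pool window exceeds image size")
    windows = sliding_window_view(pixels, (spec.window, spec.window))
    windows = windows[::spec.stride, ::spec.stride]
    reduced = windows.mean(axis=(-2, -1)) if spec.mode == "average" \
        else windows.max(axis=(-2, -1))
    origin = block.channel_origin if isinstance(block, GrayImage) else "green"
    return GrayImage(reduced, channel_origin=origin)


def filterbank_weights(conv: ConvSpec, n_rounds: int = 2) -> np.ndarray:
    """Seeded weights, shape (n_rounds, n_filters, kernel, kernel)."""
    rng = np.random.default_rng(conv.seed)
    w = rng.uniform(-1.0, 1.0,
                    size=(n_rounds, conv.n_filters, conv.kernel, conv.kernel))
    return w / conv.kernel ** 2


def filterbank_embed(g, conv: ConvSpec | None = None, pool_spec: PoolSpec | None = None,
                     out_dim: int = DEFAULT_EMBED_DIM) -> FeatureVector:
    """Two conv/rectify/pool rounds, global average per map, tiled to out_dim.

    Round 2 is depthwise: each round-1 map is convolved with its own filter.
    The ``n_filters`` global averages are tiled (repeated, then truncated) to
    exactly ``out_dim`` entries.
    """
    conv = conv or ConvSpec()
    pool_spec = pool_spec or PoolSpec()
    if out_dim < conv.n_filters:
        raise ValueError("out_dim must be >= n_filters")
    pixels = as_pixels(g)
    min_side = (pool_spec.window * pool_spec.stride) + conv.kernel
    if min(pixels.shape) < min_side:
        raise ValueError("image too small for two conv+pool rounds")
    w = filterbank_weights(conv)
    feats = np.empty(conv.n_filters)
    for f in range(conv.n_filters):
        m = np.maximum(conv2d(pixels, w[0, f], conv.stride), 0.0)
        m = pool(GrayImage(m), pool_spec).pixels
        m = np.maximum(conv2d(m, w[1, f], conv.stride), 0.0)
        m = pool(GrayImage(m), pool_spec).pixels
        feats[f] = m.mean()
    tiled = np.resize(feats, out_dim)
    return FeatureVector(tiled, (("deep", out_dim),),
                         meta={"n_filters": conv.n_filters, "seed": conv.seed})


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Fit PCA by SVD of the mean-centered matrix (equivalent to covariance
    eigendecomposition).  Components are orthonormal, ordered by decreasing
    variance, and signed so the largest-magnitude loading is positive."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    k_max = min(n - 1, d)
    if not 1 <= k <= k_max:
        raise ValueError(f"k={k} invalid; maximum feasible k is {k_max}")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    components = vt[:k]
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(components[np.arange(k), np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    components = components * flip[:, None]
    variance = (s[:k] ** 2) / (n - 1)
    return PCAModel(mean, components, variance, k)


def pca_reduce(X: np.ndarray, model: PCAModel) -> np.ndarray:
    """Centered projection onto the fitted components."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean_vector.size:
        raise ValueError(f"X has {X.shape[1]} columns, model expects "
                         f"{model.mean_vector.size}")
    return (X - model.mean_vector) @ model.component_matrix.T


class FilterBankEmbedder:
    """Transformer: enhanced gray images -> (n_samples, out_dim) embeddings."""

    def __init__(self, n_filters: int = 64, kernel: int = 5,
                 out_dim: int = DEFAULT_EMBED_DIM, seed: int = DEFAULT_SEED,
                 pool_mode: str = "average"):
        self.n_filters = n_filters
        self.kernel = kernel
        self.out_dim = out_dim
        self.seed = seed
        self.pool_mode = pool_mode

    def get_params(self, deep: bool = True) -> dict:
        return {"n_filters": self.n_filters, "kernel": self.kernel,
                "out_dim": self.out_dim, "seed": self.seed,
                "pool_mode": self.pool_mode}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        conv = ConvSpec(n_filters=self.n_filters, kernel=self.kernel,
                        seed=self.seed)
        pspec = PoolSpec(mode=self.pool_mode)
        return np.asarray([
            filterbank_embed(as_pixels(g) if isinstance(g, GrayImage) else g,
                             conv, pspec, self.out_dim).values
            for g in X])

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class PCAReducer:
    """PCA transformer with the small-corpus cap ``min(k, n-1, d)``.

    Fitted attributes: ``model_`` (:class:`PCAModel`), ``k_`` (effective
    number of components).
    """

    def __init__(self, k: int = DEFAULT_PCA_K):
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.k_ = min(self.k, X.shape[0] - 1, X.shape[1])
        self.model_ = pca_fit(X, self.k_)
        return self

    def transform(self, X) -> np.ndarray:
        return pca_reduce(X, self.model_)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
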