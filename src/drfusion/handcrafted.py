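"""Handcrafted color/texture descriptors: FCH, GLCM (Haralick) and LBP.

Three fixed-length blocks are extracted per image and concatenated into a
232-dimensional vector:

* **FCH** (fuzzy color histogram, 16) — each pixel's color index contributes
  triangular fuzzy membership to its two nearest histogram bins instead of a
  hard count.  The default index is green dominance, ``G - (R+B)/2`` rescaled
  to [0, 1], because retinal microvasculature responds most strongly in the
  green channel; a plain luminance histogram is available via ``mode``.
* **GLCM** (13) — the thirteen classical Haralick statistics of the symmetric,
  normalized gray-level co-occurrence matrix, averaged over the configured
  distances and angles (defaults: 16 levels, distance 1, angles
  0/45/90/135 degrees).
* **LBP** (203) — local binary pattern codes with 24 circularly interpolated
  neighbors at radius 2 (5x5 pixel support), labeled by the non-rotation-
  invariant uniform scheme (555 labels) and re-binned into 203 equal-width
  histogram bins.

GLCM and LBP operate on any single-channel image (typically the enhanced
green channel) after per-image min-max quantization, so they are invariant to
affine intensity changes; FCH needs color and uses the constancy-corrected
RGB image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import GrayImage, as_pixels

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2",
)

#: degree -> (row offset, col offset) for co-occurrence pairs at distance 1
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class FeatureVector:
    """A numeric vector with a named block layout, e.g. ``[("fch", 16)]``."""

    values: np.ndarray
    layout: tuple[tuple[str, int], ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.layout = tuple((str(n), int(l)) for n, l in self.layout)
        if sum(l for _, l in self.layout) != self.values.size:
            raise ValueError("layout lengths do not sum to vector length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    def block(self, name: str) -> np.ndarray:
        """Return the slice of ``values`` belonging to the named block."""
        start = 0
        for block_name, length in self.layout:
            if block_name == name:
                return self.values[start:start + length]
            start += length
        raise KeyError(name)


@dataclass
class FCHSpec:
    n_bins: int = 16
    membership: str = "triangular"
    color_space: str = "rgb"
    mode: str = "chroma"  # "chroma" (green dominance) or "luminance"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.membership != "triangular":
            raise ValueError("only triangular membership is supported")


@dataclass
class GLCMSpec:
    levels: int = 16
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if any(a not in _ANGLE_OFFSETS for a in self.angles):
            raise ValueError(f"angles must be in {sorted(_ANGLE_OFFSETS)}")


@dataclass
class LBPSpec:
    n_points: int = 24
    radius: int = 2
    n_bins: int = 203

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def n_labels(self) -> int:
        # all-zeros + all-ones + P rotations of each run length 1..P-1 + non-uniform
        return self.n_points * (self.n_points - 1) + 3


# ---------------------------------------------------------------------------
# FCH
# ---------------------------------------------------------------------------

def color_index(rgb: np.ndarray, mode: str = "chroma") -> np.ndarray:
    """Per-pixel scalar color index in [0, 1] used by the fuzzy histogram."""
    if mode == "chroma":
        raw = rgb[..., 1] - 0.5 * (rgb[..., 0] + rgb[..., 2])  # in [-1, 1]
        return (raw + 1.0) / 2.0
    if mode == "luminance":
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"unknown FCH mode {mode!r}")


def fch_features(img, spec: FCHSpec | None = None) -> FeatureVector:
    """Fuzzy color histogram: triangular membership to the two nearest bins.

    Bin centers sit at ``(i + 0.5)/n`` for i in 0..n-1; a pixel exactly on a
    center contributes 1 to that bin, a pixel midway between two centers
    contributes 0.5 to each.  The histogram is normalized to sum to 1.
    """
    spec = spec or FCHSpec()
    rgb = as_pixels(img)
    v = color_index(rgb, spec.mode).ravel()
    n = spec.n_bins
    # fractional bin position relative to the centers grid
    p = v * n - 0.5
    lower = np.floor(p).astype(int)
    frac = p - lower
    hist = np.zeros(n)
    np.add.at(hist, np.clip(lower, 0, n - 1), 1.0 - frac)
    np.add.at(hist, np.clip(lower + 1, 0, n - 1), frac)
    hist /= hist.sum()
    return FeatureVector(hist, (("fch", n),))


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

def quantize_minmax(pixels: np.ndarray, levels: int) -> tuple[np.ndarray, bool]:
    """Min-max quantize to integer levels 0..levels-1; flags constant images."""
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros(pixels.shape, dtype=int), True
    q = np.floor((pixels - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1), False


def cooccurrence_matrix(q: np.ndarray, levels: int, distance: int, angle: int,
                        symmetric: bool = True) -> np.ndarray:
    """Normalized (symmetric) co-occurrence matrix for one offset."""
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    rows = slice(max(0, -dr), q.shape[0] - max(0, dr))
    cols = slice(max(0, -dc), q.shape[1] - max(0, dc))
    a = q[rows, cols]
    b = q[rows.start + dr:rows.stop + dr, cols.start + dc:cols.stop + dc]
    counts = np.bincount((a * levels + b).ravel(), minlength=levels * levels)
    P = counts.reshape(levels, levels).astype(float)
    if symmetric:
        P = P + P.T
    total = P.sum()
    return P / total if total > 0 else P


def haralick_statistics(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of a normalized co-occurrence matrix.

    Order follows :data:`HARALICK_NAMES` (the classical f1..f13 numbering).
    Logarithms are natural; zero-probability terms contribute zero.  For a
    degenerate matrix with zero marginal variance the correlation is defined
    as 0, and the information measures fall back to 0 where their normalizers
    vanish.
    """
    L = P.shape[0]
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    def xlogx(p):
        return np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)

    # sum and difference marginals: k = i + j in 0..2L-2, d = |i - j| in 0..L-1
    p_sum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=P.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    asm = (P ** 2).sum()
    contrast = (k_diff ** 2 * p_diff).sum()
    if sd_x > 0 and sd_y > 0:
        correlation = ((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * P).sum()
    idm = (P / (1.0 + (ii - jj) ** 2)).sum()
    sum_average = (k_sum * p_sum).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * p_sum).sum()
    sum_entropy = -xlogx(p_sum).sum()
    entropy = -xlogx(P).sum()
    diff_average = (k_diff * p_diff).sum()
    difference_variance = ((k_diff - diff_average) ** 2 * p_diff).sum()
    difference_entropy = -xlogx(p_diff).sum()

    hx = -xlogx(px).sum()
    hy = -xlogx(py).sum()
    pxy = np.outer(px, py)
    logpxy = np.where(pxy > 0, np.log(pxy, where=pxy > 0, out=np.zeros_like(pxy)), 0.0)
    hxy1 = -(P * logpxy).sum()
    hxy2 = -(pxy * logpxy).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array([asm, contrast, correlation, variance, idm, sum_average,
                     sum_variance, sum_entropy, entropy, difference_variance,
                     difference_entropy, imc1, imc2])


def glcm_features(g, spec: GLCMSpec | None = None) -> FeatureVector:
    """13 Haralick statistics of the offset-averaged co-occurrence matrix."""
    spec = spec or GLCMSpec()
    pixels = as_pixels(g)
    q, constant = quantize_minmax(pixels, spec.levels)
    mats = [cooccurrence_matrix(q, spec.levels, d, a, spec.symmetric)
            for d in spec.distances for a in spec.angles]
    P = np.mean(mats, axis=0)
    values = haralick_statistics(P)
    return FeatureVector(values, (("glcm", len(HARALICK_NAMES)),),
                         meta={"constant_image": constant})


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def _neighbor_offsets(n_points: int, radius: float) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n_points) / n_points
    # (row, col) offsets; row axis points down
    return np.stack([-radius * np.sin(angles), radius * np.cos(angles)], axis=1)


def lbp_codes(g, spec: LBPSpec | None = None) -> np.ndarray:
    """Per-pixel non-rotation-invariant uniform LBP labels.

    Neighbors are sampled on a circle of ``radius`` with bilinear
    interpolation (reflect-padded borders) and thresholded at the center
    value (>=).  Uniform codes (<= 2 circular transitions) are labeled by
    (number of ones, start of the one-run); all non-uniform codes share one
    label.  Total labels: ``P*(P-1) + 3``.
    """
    spec = spec or LBPSpec()
    pixels = as_pixels(g)
    H, W = pixels.shape
    r = spec.radius
    if H <= 2 * r or W <= 2 * r:
        raise ValueError("image too small for the requested LBP radius")
    P = spec.n_points
    pad = int(np.ceil(r)) + 1  # +1: bilinear interpolation reads one past floor
    padded = np.pad(pixels, pad, mode="symmetric")
    rows = np.arange(H) + pad
    cols = np.arange(W) + pad

    bits = np.empty((P, H, W), dtype=bool)
    for k, (dr, dc) in enumerate(_neighbor_offsets(P, r)):
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        # bilinear interpolation from the four surrounding integer offsets
        val = ((1 - fr) * (1 - fc) * padded[np.ix_(rows + r0, cols + c0)]
               + (1 - fr) * fc * padded[np.ix_(rows + r0, cols + c0 + 1)]
               + fr * (1 - fc) * padded[np.ix_(rows + r0 + 1, cols + c0)]
               + fr * fc * padded[np.ix_(rows + r0 + 1, cols + c0 + 1)])
        bits[k] = val >= pixels

    transitions = (bits != np.roll(bits, 1, axis=0)).sum(axis=0)
    ones = bits.sum(axis=0)
    uniform = transitions <= 2

    labels = np.full((H, W), P * (P - 1) + 2, dtype=int)  # non-uniform label
    labels[uniform & (ones == 0)] = 0
    labels[uniform & (ones == P)] = P * (P - 1) + 1
    # run start: the unique k with bit[k]=1 and bit[k-1]=0
    run_start = np.argmax(bits & ~np.roll(bits, 1, axis=0), axis=0)
    interior = uniform & (ones > 0) & (ones < P)
    labels[interior] = 1 + (ones[interior] - 1) * P + run_start[interior]
    return labels


def lbp_features(g, spec: LBPSpec | None = None) -> FeatureVector:
    """Uniform-LBP label histogram re-binned to ``n_bins`` equal-width bins."""
    spec = spec or LBPSpec()
    labels = lbp_codes(g, spec)
    n_labels = spec.n_labels
    counts = np.bincount(labels.ravel(), minlength=n_labels).astype(float)
    # map label l -> bin floor(l * n_bins / n_labels)
    bins = (np.arange(n_labels) * spec.n_bins) // n_labels
    hist = np.bincount(bins, weights=counts, minlength=spec.n_bins)
    hist /= hist.sum()
    return FeatureVector(hist, (("lbp", spec.n_bins),))


# ---------------------------------------------------------------------------
# Concatenation and the sklearn-style extractor
# ---------------------------------------------------------------------------

HANDCRAFTED_LAYOUT = (("fch", 16), ("glcm", 13), ("lbp", 203))
HANDCRAFTED_DIM = sum(l for _, l in HANDCRAFTED_LAYOUT)


def concat_handcrafted(fch: FeatureVector, glcm: FeatureVector,
                       lbp: FeatureVector) -> FeatureVector:
    """Concatenate fch || glcm || lbp into the canonical 232-dim vector."""
    expected = dict(HANDCRAFTED_LAYOUT)
    for name, vec in (("fch", fch), ("glcm", glcm), ("lbp", lbp)):
        if len(vec) != expected[name]:
            raise ValueError(f"{name} block must have length {expected[name]}, "
                             f"got {len(vec)}")
    values = np.concatenate([fch.values, glcm.values, lbp.values])
    return FeatureVector(values, HANDCRAFTED_LAYOUT)


class HandcraftedExtractor:
    """Transformer: RGB images -> (n_samples, 232) handcrafted feature matrix.

    FCH is computed on the gray-world corrected RGB image; GLCM and LBP on
    the enhanced green channel (mean-minus-Laplacian fusion).
    """

    def __init__(self, kernel_size: int = 4, fch_spec: FCHSpec | None = None,
                 glcm_spec: GLCMSpec | None = None, lbp_spec: LBPSpec | None = None):
        self.kernel_size = kernel_size
        self.fch_spec = fch_spec
        self.glcm_spec = glcm_spec
        self.lbp_spec = lbp_spec

    def get_params(self, deep: bool = True) -> dict:
        return {"kernel_size": self.kernel_size, "fch_spec": self.fch_spec,
                "glcm_spec": self.glcm_spec, "lbp_spec": self.lbp_spec}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        from .preprocess import AverageFilterSpec, enhance, gray_world_constancy

        spec = AverageFilterSpec(kernel_size=self.kernel_size)
        rows = []
        for img in X:
            corrected = gray_world_constancy(img)
            enhanced = enhance(img, spec)
            vec = concat_handcrafted(
                fch_features(corrected, self.fch_spec),
                glcm_features(enhanced, self.glcm_spec),
                lbp_features(enhanced, self.lbp_spec),
            )
            rows.append(vec.values)
        return np.asarray(rows)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
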