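"""Fundus image enhancement.

The enhancement chain is: gray-world color constancy on the RGB image, green
channel extraction (the green channel carries the strongest microvasculature
contrast in fundus photography), then a fusion of two filter responses,

    enhanced = mean_filter(g) - laplacian(g),

i.e. a noise-suppressed copy of the green channel minus its 4-neighbor
Laplacian, which sharpens vessel edges and dark lesions.  The default mean
filter is a 4x4 box normalized by the true pixel count (16); even kernels are
anchored at the top-left pixel of the 2x2 center block and all borders use
reflect padding, so outputs are shape-preserving and deterministic.

The enhanced image is kept real-valued (the Laplacian term is signed); use
:func:`drfusion.image.save_gray16` for a rescaled visual export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .image import GrayImage, ImageRGB, as_pixels

LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class AverageFilterSpec:
    """Box (mean) filter parameters; ``kernel_size`` may be even."""

    kernel_size: int = 4
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")
        if self.border_mode != "reflect":
            raise ValueError("only reflect borders are supported")


def gray_world_constancy(img) -> ImageRGB:
    """Rescale each channel so all channel means equal the global mean.

    The unclipped result has equal channel means; output is clipped to [0, 1].
    A channel whose mean is zero cannot be rescaled and raises ``ValueError``.
    """
    src = img if isinstance(img, ImageRGB) else ImageRGB(as_pixels(img))
    means = src.pixels.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0.0):
        raise ValueError("degenerate channel: zero mean, cannot rescale")
    scaled = src.pixels * (means.mean() / means)
    return ImageRGB(np.clip(scaled, 0.0, 1.0), label=src.label, id=src.id)


def extract_green(img) -> GrayImage:
    """Return the green channel unchanged as a :class:`GrayImage`."""
    pixels = as_pixels(img)
    return GrayImage(pixels[..., 1].copy(), channel_origin="green")


def extract_luminance(img) -> GrayImage:
    """ITU-R BT.601 luminance; alternative source channel for enhancement."""
    pixels = as_pixels(img)
    lum = pixels @ np.array([0.299, 0.587, 0.114])
    return GrayImage(lum, channel_origin="luminance")


def mean_filter(g, spec: AverageFilterSpec | None = None) -> GrayImage:
    """Local arithmetic mean over a ``kernel_size`` square window.

    Each output pixel is the mean of the k*k reflect-padded neighborhood; for
    even k the window spans offsets ``-(k//2 - 1) .. k//2`` in each axis
    (anchor at the top-left of the central 2x2 block).
    """
    spec = spec or AverageFilterSpec()
    pixels = as_pixels(g)
    k = spec.kernel_size
    if k > min(pixels.shape):
        raise ValueError(f"kernel_size {k} exceeds image side {min(pixels.shape)}")
    before = (k - 1) // 2
    after = k - 1 - before
    padded = np.pad(pixels, ((before, after), (before, after)), mode="symmetric")
    out = sliding_window_view(padded, (k, k)).mean(axis=(-2, -1))
    origin = g.channel_origin if isinstance(g, GrayImage) else "green"
    return GrayImage(out, channel_origin=origin)


def laplacian(g) -> GrayImage:
    """Discrete 4-neighbor Laplacian with reflect borders; output is signed."""
    pixels = as_pixels(g)
    out = ndimage.convolve(pixels, LAPLACIAN_KERNEL, mode="reflect")
    origin = g.channel_origin if isinstance(g, GrayImage) else "green"
    return GrayImage(out, channel_origin=origin)


def enhance(img, spec: AverageFilterSpec | None = None, *, channel: str = "green",
            color_constancy: bool = True) -> GrayImage:
    """Full enhancement: constancy -> channel extraction -> mean minus Laplacian."""
    spec = spec or AverageFilterSpec()
    rgb = gray_world_constancy(img) if color_constancy else (
        img if isinstance(img, ImageRGB) else ImageRGB(as_pixels(img)))
    g = extract_green(rgb) if channel == "green" else extract_luminance(rgb)
    fused = mean_filter(g, spec).pixels - laplacian(g).pixels
    return GrayImage(fused, channel_origin=g.channel_origin,
                     meta={"kernel_size": spec.kernel_size})


class FundusEnhancer:
    """Stateless scikit-learn style transformer applying :func:`enhance`.

    ``transform`` maps a sequence of RGB images (arrays or :class:`ImageRGB`)
    to a list of enhanced :class:`GrayImage`.
    """

    def __init__(self, kernel_size: int = 4, channel: str = "green",
                 color_constancy: bool = True):
        self.kernel_size = kernel_size
        self.channel = channel
        self.color_constancy = color_constancy

    def get_params(self, deep: bool = True) -> dict:
        return {"kernel_size": self.kernel_size, "channel": self.channel,
                "color_constancy": self.color_constancy}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> list[GrayImage]:
        spec = AverageFilterSpec(kernel_size=self.kernel_size)
        return [enhance(img, spec, channel=self.channel,
                        color_constancy=self.color_constancy) for img in X]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
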