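"""Core image containers and validation.

Fundus photographs are handled as float arrays with intensities in [0, 1]:
``ImageRGB`` wraps an HxWx3 color image together with its diabetic-retinopathy
grade (0 = normal ... 4 = proliferative), ``GrayImage`` wraps a single-channel
image.  Gray images produced by the enhancement stage are real-valued and may
leave [0, 1] (the Laplacian term is signed), so only finiteness is enforced
there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Canonical five-stage grading used throughout the package.
CLASS_NAMES = ("normal", "mild", "moderate", "severe", "proliferative")
N_CLASSES = len(CLASS_NAMES)

MIN_SIDE = 8


@dataclass
class ImageRGB:
    """An RGB fundus image with optional grade label and identifier."""

    pixels: np.ndarray
    label: int | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        validate_rgb(self.pixels)
        if self.label is not None and self.label not in range(N_CLASSES):
            raise ValueError(f"label must be in 0..{N_CLASSES - 1}, got {self.label}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def class_name(self) -> str | None:
        return None if self.label is None else CLASS_NAMES[self.label]


@dataclass
class GrayImage:
    """A single-channel image; ``channel_origin`` records how it was derived."""

    pixels: np.ndarray
    channel_origin: str = "green"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage expects an HxW array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def validate_rgb(pixels: np.ndarray) -> None:
    """Raise ``ValueError`` unless *pixels* is a valid HxWx3 image in [0, 1]."""
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 array, got shape {pixels.shape}")
    if pixels.shape[0] < MIN_SIDE or pixels.shape[1] < MIN_SIDE:
        raise ValueError(f"image sides must be >= {MIN_SIDE}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite values")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")


def as_pixels(img) -> np.ndarray:
    """Accept an ``ImageRGB``/``GrayImage`` or a bare array; return the array."""
    if isinstance(img, (ImageRGB, GrayImage)):
        return img.pixels
    return np.asarray(img, dtype=float)


def load_rgb(path: str | Path, label: int | None = None) -> ImageRGB:
    """Read a PNG/JPEG/TIFF file into an ``ImageRGB`` scaled to [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[..., :3]
    info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
    pixels = raw.astype(float) / (info.max if info else 1.0)
    return ImageRGB(np.clip(pixels, 0.0, 1.0), label=label, id=Path(path).stem)


def save_rgb(img: ImageRGB, path: str | Path) -> None:
    """Write an ``ImageRGB`` as an 8-bit PNG."""
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def save_gray16(g: GrayImage, path: str | Path, sidecar: dict | None = None) -> None:
    """Export a real-valued gray image as 16-bit PNG, min-max rescaled.

    A JSON sidecar next to the PNG records the rescaling limits and any
    processing parameters so the export is invertible up to quantization.
    """
    path = Path(path)
    lo, hi = float(g.pixels.min()), float(g.pixels.max())
    span = hi - lo if hi > lo else 1.0
    arr = np.round((g.pixels - lo) / span * 65535.0).astype(np.uint16)
    iio.imwrite(path, arr)
    record = {"min": lo, "max": hi, "channel_origin": g.channel_origin}
    if sidecar:
        record.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(record, indent=2))
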