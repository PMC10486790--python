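"""Seeded synthetic fundus-like image generator.

Each image is an orange-tinted retinal disc on a black background with
low-frequency illumination noise, a bright optic disc and a branching
dark-red vessel tree.  On top of that, stage-dependent lesions follow the
clinical grading semantics:

==============  ==============================================================
normal          no lesions
mild            a light scattering of microaneurysms (small red dots)
moderate        more microaneurysms plus hemorrhage blobs and a few exudates
severe          dense microaneurysms, many hemorrhages and exudates
proliferative   all of the above plus tortuous bright neovascular curves
==============  ==============================================================

Lesion counts are Poisson with a rate that rises strictly with severity, so
classes are separable by color/texture statistics by construction.
Microaneurysm dots use radius 1-2 px and hemorrhage blobs 3-6 px so lesions
survive the 4x4 mean filter of the enhancement stage.  Everything is driven
by one seed (per-image streams are spawned from it), so a corpus is
byte-identical across runs.

This generator is a test-scale instrument, not a photorealistic simulator:
there is no camera model, no inter-patient anatomy variation and no grader
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import CLASS_NAMES, ImageRGB

#: per-class Poisson rates: microaneurysm dots, hemorrhage blobs,
#: exudate specks, neovascular curves.  Dot rate is strictly increasing
#: with severity; neovascularization only appears in the proliferative class.
LESION_RATES = {
    "normal": {"micro": 0.0, "hem": 0.0, "exu": 0.0, "neo": 0.0},
    "mild": {"micro": 8.0, "hem": 0.0, "exu": 0.0, "neo": 0.0},
    "moderate": {"micro": 18.0, "hem": 4.0, "exu": 3.0, "neo": 0.0},
    "severe": {"micro": 30.0, "hem": 10.0, "exu": 8.0, "neo": 0.0},
    "proliferative": {"micro": 40.0, "hem": 14.0, "exu": 10.0, "neo": 4.0},
}

BACKGROUND_RGB = np.array([0.82, 0.46, 0.13])
VESSEL_RGB = np.array([0.45, 0.12, 0.08])
MICRO_RGB = np.array([0.50, 0.10, 0.10])
HEM_RGB = np.array([0.35, 0.05, 0.05])
EXUDATE_RGB = np.array([0.95, 0.88, 0.40])
NEO_RGB = np.array([0.85, 0.25, 0.20])


@dataclass
class SynthSpec:
    n_per_class: int = 20
    image_size: int = 128
    seed: int = 0
    lesion_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(LESION_RATES[c]) for c in CLASS_NAMES})

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        micro = [self.lesion_rates[c]["micro"] for c in CLASS_NAMES]
        if any(b < a for a, b in zip(micro, micro[1:])):
            raise ValueError("microaneurysm rate must be non-decreasing "
                             "with severity")


def _disc_mask(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def _stamp_disc(img: np.ndarray, center: tuple[float, float], radius: float,
                color: np.ndarray, alpha: float = 1.0) -> None:
    """Alpha-blend a filled disc; only touches its bounding box."""
    size = img.shape[0]
    y0 = max(0, int(np.floor(center[0] - radius)))
    y1 = min(size, int(np.ceil(center[0] + radius)) + 1)
    x0 = max(0, int(np.floor(center[1] - radius)))
    x1 = min(size, int(np.ceil(center[1] + radius)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
    patch = img[y0:y1, x0:x1]
    patch[mask] = (1.0 - alpha) * patch[mask] + alpha * color


def _random_point_in_aperture(rng, size: int, margin: float = 0.82) -> tuple[int, int]:
    center = size / 2.0
    radius = 0.48 * size * margin
    while True:
        y, x = rng.uniform(-radius, radius, 2)
        if y * y + x * x <= radius * radius:
            return int(center + y), int(center + x)


def _draw_curve(img: np.ndarray, rng, start: tuple[float, float], size: int,
                color: np.ndarray, n_steps: int, wiggle: float,
                width: float, alpha: float = 0.9) -> None:
    """Stamp small discs along a random-curvature walk (a vessel segment)."""
    y, x = float(start[0]), float(start[1])
    theta = rng.uniform(0.0, 2.0 * np.pi)
    for _ in range(n_steps):
        theta += rng.normal(0.0, wiggle)
        y += np.sin(theta)
        x += np.cos(theta)
        if not (1 <= y < size - 1 and 1 <= x < size - 1):
            break
        _stamp_disc(img, (y, x), width, color, alpha)


def _background(rng, size: int) -> tuple[np.ndarray, np.ndarray]:
    center = size / 2.0
    aperture = _disc_mask(size, (center, center), 0.48 * size)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.sqrt((yy - center) ** 2 + (xx - center) ** 2) / (0.48 * size)
    falloff = np.clip(1.0 - 0.35 * r ** 2, 0.0, 1.0)
    img = np.zeros((size, size, 3))
    for c in range(3):
        noise = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                        sigma=size / 16.0)
        noise = noise / (np.abs(noise).max() + 1e-12)
        img[..., c] = BACKGROUND_RGB[c] * falloff * (1.0 + 0.08 * noise)
    # fine-grained sensor noise so texture statistics are not degenerate
    img += rng.normal(0.0, 0.01, size=img.shape)
    img[~aperture] = 0.0
    return np.clip(img, 0.0, 1.0), aperture


def _vessel_tree(img: np.ndarray, rng, size: int) -> None:
    # optic disc: bright yellowish spot off-center
    disc_center = (size * 0.5 + rng.uniform(-3, 3), size * 0.72 + rng.uniform(-3, 3))
    _stamp_disc(img, disc_center, size * 0.055,
                np.array([0.95, 0.85, 0.55]), alpha=0.9)
    for _ in range(6):
        _draw_curve(img, rng, disc_center, size, VESSEL_RGB,
                    n_steps=int(size * 0.9), wiggle=0.18,
                    width=rng.uniform(0.8, 1.4), alpha=0.85)


def generate_image(label: int, size: int, rng: np.random.Generator,
                   rates: dict[str, float] | None = None,
                   stats: dict | None = None) -> np.ndarray:
    """One synthetic fundus image for the given grade; pixels in [0, 1].

    If ``stats`` is a dict, the sampled lesion counts are recorded in it
    (keys ``micro``/``hem``/``exu``/``neo``).
    """
    rates = rates or LESION_RATES[CLASS_NAMES[label]]
    img, aperture = _background(rng, size)
    _vessel_tree(img, rng, size)

    counts = {key: int(rng.poisson(rates[key]))
              for key in ("micro", "hem", "exu", "neo")}
    if stats is not None:
        stats.update(counts)
    for _ in range(counts["micro"]):
        pos = _random_point_in_aperture(rng, size)
        _stamp_disc(img, pos, rng.uniform(1.0, 2.0), MICRO_RGB, 0.9)
    for _ in range(counts["hem"]):
        pos = _random_point_in_aperture(rng, size)
        # irregular blob: union of 2-3 overlapping discs
        for _ in range(rng.integers(2, 4)):
            jitter = rng.normal(0.0, 1.5, 2)
            _stamp_disc(img, (pos[0] + jitter[0], pos[1] + jitter[1]),
                        rng.uniform(3.0, 6.0), HEM_RGB, 0.85)
    for _ in range(counts["exu"]):
        pos = _random_point_in_aperture(rng, size)
        _stamp_disc(img, pos, rng.uniform(1.0, 3.0), EXUDATE_RGB, 0.9)
    for _ in range(counts["neo"]):
        start = _random_point_in_aperture(rng, size)
        _draw_curve(img, rng, start, size, NEO_RGB, n_steps=int(size * 0.4),
                    wiggle=0.55, width=0.9, alpha=0.9)

    img[~aperture] = 0.0
    return np.clip(img, 0.0, 1.0)


def generate_corpus(spec: SynthSpec) -> tuple[list[ImageRGB], pd.DataFrame]:
    """A labeled corpus of ``n_per_class`` images per grade plus a manifest.

    Per-image random streams are spawned from ``spec.seed``, so the corpus is
    reproducible regardless of generation order.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(5 * spec.n_per_class)
    images: list[ImageRGB] = []
    rows = []
    idx = 0
    for label, name in enumerate(CLASS_NAMES):
        for j in range(spec.n_per_class):
            rng = np.random.default_rng(seeds[idx])
            pixels = generate_image(label, spec.image_size, rng,
                                    spec.lesion_rates[name])
            img_id = f"{name}_{j:04d}"
            images.append(ImageRGB(pixels, label=label, id=img_id))
            rows.append({"id": img_id, "class": name, "label": label,
                         "provenance": "synthetic"})
            idx += 1
    manifest = pd.DataFrame(rows)
    return images, manifest
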