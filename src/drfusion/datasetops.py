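"""Dataset curation, splitting and class-balancing augmentation.

The study design these operations implement:

* **Curation** — the public grading corpora are dominated by healthy eyes, so
  only a fraction (default 10%) of the normal class is kept, sampled
  uniformly without replacement.
* **Splitting** — per class: 20% test, then 20% of the remainder for
  validation, the rest for training.  Sizes use round-half-up; image-to-
  partition assignment is seeded and stratified.
* **Augmentation** — the training partition only is expanded with fixed
  per-class factors (normal 3, mild 3, moderate 1, severe 11, proliferative
  13 extra images per original), which balances the five classes.  Transforms
  are small rotations (5-25 degrees either way), horizontal/vertical flips
  and shifts of up to 5% of the image side, reflect-filled so lesion content
  is preserved and output shape never changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import CLASS_NAMES, ImageRGB, as_pixels

#: extra images generated per original, per class (training partition only)
DEFAULT_AUG_FACTORS = {"normal": 3, "mild": 3, "moderate": 1,
                       "severe": 11, "proliferative": 13}

PARTITIONS = ("train", "validation", "test")


def round_half_up(x: float) -> int:
    """Round with ties going up (2.5 -> 3), unlike banker's rounding."""
    return int(math.floor(x + 0.5))


@dataclass
class ClassCounts:
    """Per-class image counts over the five grades."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        self.counts = {name: int(self.counts.get(name, 0)) for name in CLASS_NAMES}

    def __getitem__(self, name: str) -> int:
        return self.counts[name]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class SplitPlan:
    """Per-class (train, validation, test) sizes plus the split parameters."""

    per_class: dict[str, tuple[int, int, int]]
    test_fraction: float = 0.2
    val_fraction: float = 0.2
    seed: int = 0

    def train_counts(self) -> ClassCounts:
        return ClassCounts({c: t[0] for c, t in self.per_class.items()})

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, *self.per_class[c]) for c in CLASS_NAMES if c in self.per_class],
            columns=["class", "train", "validation", "test"])


@dataclass
class AugmentationPlan:
    """Per-class augmentation factors and the resulting post-counts."""

    factors: dict[str, int]
    pre_counts: dict[str, int]
    post_counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.post_counts:
            self.post_counts = {c: n * (self.factors[c] + 1)
                                for c, n in self.pre_counts.items()}


def curate_normals(raw: ClassCounts, keep_fraction: float = 0.1) -> ClassCounts:
    """Subsample the normal class to ``keep_fraction`` (round-half-up)."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if raw["normal"] == 0:
        raise ValueError("normal class is empty; nothing to curate")
    kept = dict(raw.counts)
    kept["normal"] = round_half_up(keep_fraction * raw["normal"])
    return ClassCounts(kept)


def curate_manifest(manifest: pd.DataFrame, keep_fraction: float = 0.1,
                    seed: int = 0) -> pd.DataFrame:
    """Drop a seeded uniform sample of normal rows; other classes untouched."""
    normals = manifest.index[manifest["class"] == "normal"].to_numpy()
    if normals.size == 0:
        raise ValueError("normal class is empty; nothing to curate")
    n_keep = round_half_up(keep_fraction * normals.size)
    rng = np.random.default_rng(seed)
    keep = rng.choice(normals, size=n_keep, replace=False)
    drop = np.setdiff1d(normals, keep)
    return manifest.drop(index=drop).reset_index(drop=True)


def split_plan(counts: ClassCounts, test_fraction: float = 0.2,
               val_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Deterministic per-class split sizes: test, then validation, then train."""
    if not (0.0 < test_fraction < 1.0 and 0.0 < val_fraction < 1.0):
        raise ValueError("fractions must be in (0, 1)")
    per_class: dict[str, tuple[int, int, int]] = {}
    for name in CLASS_NAMES:
        n = counts[name]
        if n == 0:
            continue
        test = round_half_up(test_fraction * n)
        val = round_half_up(val_fraction * (n - test))
        train = n - test - val
        if min(train, val, test) <= 0:
            raise ValueError(f"class {name!r} (n={n}) yields an empty partition")
        per_class[name] = (train, val, test)
    return SplitPlan(per_class, test_fraction, val_fraction, seed)


def assign_partitions(manifest: pd.DataFrame, plan: SplitPlan) -> pd.DataFrame:
    """Add a ``partition`` column: seeded stratified disjoint assignment."""
    out = manifest.copy()
    out["partition"] = ""
    rng = np.random.default_rng(plan.seed)
    for name, (train, val, test) in plan.per_class.items():
        idx = out.index[out["class"] == name].to_numpy()
        if idx.size != train + val + test:
            raise ValueError(f"class {name!r}: manifest has {idx.size} rows, "
                             f"plan expects {train + val + test}")
        perm = rng.permutation(idx)
        out.loc[perm[:test], "partition"] = "test"
        out.loc[perm[test:test + val], "partition"] = "validation"
        out.loc[perm[test + val:], "partition"] = "train"
    return out


def augmentation_plan(train_counts: ClassCounts,
                      factors: dict[str, int] | None = None,
                      seed: int = 0) -> AugmentationPlan:
    """Fixed per-class balancing factors applied to training counts."""
    factors = dict(DEFAULT_AUG_FACTORS if factors is None else factors)
    unknown = set(factors) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if any(f < 0 for f in factors.values()):
        raise ValueError("factors must be >= 0")
    pre = {c: n for c, n in train_counts.counts.items() if n > 0}
    if not pre:
        raise ValueError("train counts are empty")
    return AugmentationPlan({c: int(factors.get(c, 0)) for c in pre}, pre, seed=seed)


# ---------------------------------------------------------------------------
# image-level transforms
# ---------------------------------------------------------------------------

def hflip(pixels: np.ndarray) -> np.ndarray:
    return pixels[:, ::-1].copy()


def vflip(pixels: np.ndarray) -> np.ndarray:
    return pixels[::-1].copy()


def rotate(pixels: np.ndarray, degrees: float) -> np.ndarray:
    out = ndimage.rotate(pixels, degrees, axes=(1, 0), reshape=False,
                         order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def shift(pixels: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = ndimage.shift(pixels, (dy, dx, 0), order=0, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def apply_augmentation(img: ImageRGB, k: int, seed: int = 0) -> list[ImageRGB]:
    """Generate ``k`` distinct seeded transforms of one training image.

    Each copy applies one transform drawn from {rotation with magnitude in
    5-25 degrees (either sign), horizontal flip, vertical flip, shift of at
    most 5% of the side}; flips are used at most once each so the k outputs
    are pairwise distinct.  Labels are preserved.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    pixels = as_pixels(img)
    rng = np.random.default_rng(seed)
    side = min(pixels.shape[:2])
    max_shift = max(1, int(0.05 * side))
    out: list[ImageRGB] = []
    used: set[tuple] = set()
    while len(out) < k:
        kind = rng.choice(["rotation", "hflip", "vflip", "shift"])
        if kind == "rotation":
            theta = rng.uniform(5.0, 25.0) * rng.choice([-1.0, 1.0])
            key = ("rotation", round(theta, 6))
            transformed = rotate(pixels, theta)
        elif kind == "hflip":
            key = ("hflip",)
            transformed = hflip(pixels)
        elif kind == "vflip":
            key = ("vflip",)
            transformed = vflip(pixels)
        else:
            dy = int(rng.integers(-max_shift, max_shift + 1))
            dx = int(rng.integers(-max_shift, max_shift + 1))
            if dy == 0 and dx == 0:
                continue
            key = ("shift", dy, dx)
            transformed = shift(pixels, dy, dx)
        if key in used:
            continue
        used.add(key)
        out.append(ImageRGB(transformed, label=img.label,
                            id=f"{img.id}_aug{len(out)}"))
    return out
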