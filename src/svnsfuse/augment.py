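"""Class-imbalance handling: rich/poor partition and online augmentation.

Dermoscopy benchmarks are severely imbalanced — a handful of majority
("rich") classes dominates the image count while minority ("poor") classes
hold only a few hundred instances each.  Instead of augmenting everything,
classes are split by an instance-count threshold and only poor-class images
receive spatial/photometric augmentation, applied on the fly during
streaming so no augmented copy is ever persisted.

The augmentation bank covers rotation, horizontal/vertical flip, random
crop, brightness, contrast, pixel jitter, aspect-ratio stretch, shear, zoom,
and vertical/horizontal shift.  Operators run in a fixed order (geometric
first, then photometric) and every draw is seeded, so a given (spec, seed)
pair always produces the same image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize, rotate, warp

__all__ = [
    "ClassInventory",
    "RichPoorPartition",
    "AugmentationSpec",
    "partition_rich_poor",
    "augment_image",
    "balanced_stream",
]


@dataclass(frozen=True)
class ClassInventory:
    """Per-class instance counts."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        counts = {str(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("instance counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_labels(cls, labels: Iterable) -> "ClassInventory":
        counts: dict[str, int] = {}
        for label in labels:
            counts[str(label)] = counts.get(str(label), 0) + 1
        return cls(counts)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"label": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClassInventory":
        frame = pd.read_csv(path)
        return cls(dict(zip(frame["label"].astype(str), frame["count"].astype(int))))


@dataclass(frozen=True)
class RichPoorPartition:
    """Disjoint rich/poor label sets with exact (rational) dataset fractions."""

    rich: frozenset[str]
    poor: frozenset[str]
    threshold: int
    rich_fraction: Fraction
    poor_fraction: Fraction

    def __post_init__(self) -> None:
        if self.rich & self.poor:
            raise ValueError("rich and poor sets overlap")
        if self.rich_fraction + self.poor_fraction != 1:
            raise ValueError("fractions must sum to 1")


def partition_rich_poor(inventory: ClassInventory, threshold: int = 1000) -> RichPoorPartition:
    """Split classes at an instance-count threshold.

    Classes with fewer than ``threshold`` instances form the poor set and
    become augmentation candidates; the rest are rich and pass through
    untouched.  Fractions are computed exactly from the counts.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if not inventory.counts:
        raise ValueError("empty class inventory")
    poor = frozenset(c for c, n in inventory.counts.items() if n < threshold)
    rich = frozenset(inventory.counts) - poor
    total = inventory.total
    poor_total = sum(inventory.counts[c] for c in poor)
    poor_fraction = Fraction(poor_total, total) if total else Fraction(0)
    return RichPoorPartition(
        rich=rich,
        poor=poor,
        threshold=int(threshold),
        rich_fraction=1 - poor_fraction,
        poor_fraction=poor_fraction,
    )


@dataclass(frozen=True)
class AugmentationSpec:
    """Operator toggles and parameter ranges for one augmentation draw.

    Magnitudes are symmetric ranges around the identity: rotation and shear
    in degrees, shift as a fraction of image size, zoom/aspect as scale
    ranges, brightness/contrast as relative strengths, jitter as the
    standard deviation of additive Gaussian noise on [0, 1] pixels.  Set a
    field to 0 (or a probability to 0) to disable that operator.
    """

    rotation_deg: float = 30.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    shear_deg: float = 10.0
    zoom_range: tuple[float, float] = (0.8, 1.2)
    aspect_range: tuple[float, float] = (0.9, 1.1)
    shift_frac: float = 0.1
    crop_frac: float = 0.9
    brightness: float = 0.2
    contrast: float = 0.2
    jitter_sigma: float = 0.02

    def __post_init__(self) -> None:
        for name in ("zoom_range", "aspect_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if not (0 < self.crop_frac <= 1):
            raise ValueError(f"crop_frac must be in (0, 1], got {self.crop_frac}")
        for name in ("hflip_prob", "vflip_prob"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be a probability, got {p}")

    @classmethod
    def identity(cls) -> "AugmentationSpec":
        """A spec under which augment_image is a no-op."""
        return cls(
            rotation_deg=0.0,
            hflip_prob=0.0,
            vflip_prob=0.0,
            shear_deg=0.0,
            zoom_range=(1.0, 1.0),
            aspect_range=(1.0, 1.0),
            shift_frac=0.0,
            crop_frac=1.0,
            brightness=0.0,
            contrast=0.0,
            jitter_sigma=0.0,
        )


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise ValueError(f"expected a non-empty HxW or HxWxC image, got shape {arr.shape}")
    return arr


def augment_image(image, spec: AugmentationSpec, seed: int) -> np.ndarray:
    """Apply one seeded augmentation draw; output keeps the input size.

    Geometric operators run first (flips, then a single centered affine
    combining rotation/shear/zoom/aspect/shift, then random crop resized
    back), photometric last (brightness, contrast, Gaussian pixel jitter).
    Pixel values are treated as [0, 1] intensities and clipped after the
    photometric stage.
    """
    arr = _as_image(image)
    rng = np.random.default_rng(seed)
    h, w = arr.shape[:2]

    # parameter draws happen unconditionally, in a fixed order, so that
    # toggling one operator never shifts the draws of the others
    angle = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
    do_hflip = rng.random() < spec.hflip_prob
    do_vflip = rng.random() < spec.vflip_prob
    shear = np.deg2rad(rng.uniform(-spec.shear_deg, spec.shear_deg))
    zoom = rng.uniform(*spec.zoom_range)
    aspect = rng.uniform(*spec.aspect_range)
    shift_y = rng.uniform(-spec.shift_frac, spec.shift_frac) * h
    shift_x = rng.uniform(-spec.shift_frac, spec.shift_frac) * w
    crop_y = rng.random()
    crop_x = rng.random()
    bright = rng.uniform(-spec.brightness, spec.brightness)
    contr = 1.0 + rng.uniform(-spec.contrast, spec.contrast)

    if do_hflip:
        arr = arr[:, ::-1].copy()
    if do_vflip:
        arr = arr[::-1].copy()

    needs_affine = (
        angle != 0.0 or shear != 0.0 or zoom != 1.0 or aspect != 1.0
        or shift_x != 0.0 or shift_y != 0.0
    )
    if needs_affine:
        center = np.array([w / 2 - 0.5, h / 2 - 0.5])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(
                rotation=np.deg2rad(angle),
                shear=shear,
                scale=(zoom * aspect, zoom / aspect),
            )
            + AffineTransform(translation=center + np.array([shift_x, shift_y]))
        )
        arr = warp(arr, tf.inverse, mode="reflect", order=1, preserve_range=True)

    if spec.crop_frac < 1.0:
        ch = max(1, int(round(h * spec.crop_frac)))
        cw = max(1, int(round(w * spec.crop_frac)))
        top = int(round(crop_y * (h - ch)))
        left = int(round(crop_x * (w - cw)))
        cropped = arr[top : top + ch, left : left + cw]
        arr = resize(cropped, (h, w) + arr.shape[2:], order=1, preserve_range=True,
                     anti_aliasing=False)

    if bright != 0.0:
        arr = arr + bright
    if contr != 1.0:
        arr = (arr - arr.mean()) * contr + arr.mean()
    if spec.jitter_sigma > 0.0:
        arr = arr + rng.normal(0.0, spec.jitter_sigma, size=arr.shape)
    if bright != 0.0 or contr != 1.0 or spec.jitter_sigma > 0.0:
        arr = np.clip(arr, 0.0, 1.0)
    return arr


def balanced_stream(
    dataset: Sequence[tuple[np.ndarray, str]] | Mapping[str, Sequence[np.ndarray]],
    partition: RichPoorPartition,
    spec: AugmentationSpec | None = None,
    seed: int = 0,
    epochs: int = 1,
) -> Iterator[tuple[np.ndarray, str]]:
    """Stream (image, label) pairs with on-the-fly poor-class augmentation.

    Rich-class images are yielded untouched (same array object); poor-class
    images receive a fresh seeded augmentation each epoch.  Nothing is
    written to disk.  The dataset may be a sequence of (image, label) pairs
    or a mapping label -> list of images.
    """
    spec = spec or AugmentationSpec()
    if isinstance(dataset, Mapping):
        pairs = [(img, label) for label, imgs in dataset.items() for img in imgs]
    else:
        pairs = list(dataset)
    for epoch in range(epochs):
        for idx, (image, label) in enumerate(pairs):
            if str(label) in partition.poor:
                child = np.random.SeedSequence(
                    entropy=seed, spawn_key=(epoch, idx)
                ).generate_state(1)[0]
                yield augment_image(image, spec, int(child) % (2**31)), label
            else:
                yield image, label
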