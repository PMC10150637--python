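"""Synthetic data generators and packaged reference fixtures.

Real two-view deep features (fused activations from two CNN backbones) are
large and require pretrained weights; for development and testing this
module emulates them with class-conditional Gaussian clusters.  Each class
gets a mean placed ``separation`` within-class standard deviations from the
origin along its own axis, and the two views share labels and instance
order but draw independent noise (with independently tunable noise scales),
so view quality — and hence true/false ensemble disagreement — can be
controlled.

Also packaged: an eight-image worked example of true/false score matrices
with ground-truth labels from the eight-class dermoscopy task (classes AK,
BCC, BKL, DF, MEL, NV, SCC, VASC), used throughout the documentation and
tests to pin down the neutrosophic resolution arithmetic, and the ISIC 2019
class inventory for imbalance-handling examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .augment import ClassInventory
from .fusion import FeatureMapStack
from .svns import Polarity, ScoreMatrix
from .tables import FeatureTable

__all__ = [
    "DERMOSCOPY_CLASSES",
    "ISIC_2019_COUNTS",
    "SyntheticSpec",
    "gen_two_view_features",
    "gen_feature_map_stacks",
    "worked_example",
    "gen_imbalanced_inventory",
]

#: Alphabetical eight-class dermoscopy label order used throughout.
DERMOSCOPY_CLASSES = ("AK", "BCC", "BKL", "DF", "MEL", "NV", "SCC", "VASC")

#: Published ISIC 2019 per-class image counts (25,331 images in total).
ISIC_2019_COUNTS = {
    "AK": 867,
    "BCC": 3323,
    "BKL": 2624,
    "DF": 239,
    "MEL": 4522,
    "NV": 12875,
    "SCC": 628,
    "VASC": 253,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the two-view Gaussian feature generator.

    ``instances_per_class`` may be a single count or one count per class
    (for imbalanced designs).  ``separation`` is the distance of each class
    mean from the origin in units of the within-class standard deviation;
    distinct class means then sit ``separation * sqrt(2)`` sd apart.
    ``view_noise`` scales the within-class sd per view, so an inferior view
    can be emulated by a scale > 1.
    """

    n_classes: int = 8
    features_per_view: int = 16
    instances_per_class: int | tuple[int, ...] = 100
    separation: float = 4.0
    view_noise: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.features_per_view < 1:
            raise ValueError("need at least one feature per view")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        counts = self.instances_per_class
        if isinstance(counts, int):
            counts = (counts,) * self.n_classes
        counts = tuple(int(c) for c in counts)
        if len(counts) != self.n_classes or any(c < 1 for c in counts):
            raise ValueError("instances_per_class must be positive, one per class")
        object.__setattr__(self, "instances_per_class", counts)
        names = tuple(self.class_names) or (
            DERMOSCOPY_CLASSES
            if self.n_classes == 8
            else tuple(f"C{j + 1}" for j in range(self.n_classes))
        )
        if len(names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        object.__setattr__(self, "class_names", names)


def _class_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n, d = spec.n_classes, spec.features_per_view
    if d >= n:
        means = np.zeros((n, d))
        means[np.arange(n), np.arange(n)] = spec.separation
        return means
    # fewer features than classes: random unit directions at the stated radius
    dirs = rng.normal(size=(n, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return spec.separation * dirs


def gen_two_view_features(spec: SyntheticSpec) -> tuple[FeatureTable, FeatureTable]:
    """Two aligned labeled feature tables with independent per-view noise."""
    rng = np.random.default_rng(spec.seed)
    means = _class_means(spec, rng)
    labels = np.concatenate(
        [
            np.repeat(spec.class_names[k], count)
            for k, count in enumerate(spec.instances_per_class)
        ]
    )
    label_idx = np.concatenate(
        [np.repeat(k, count) for k, count in enumerate(spec.instances_per_class)]
    )
    n_total = label_idx.size
    views = []
    for noise_scale in spec.view_noise:
        noise = rng.normal(size=(n_total, spec.features_per_view)) * noise_scale
        views.append(
            FeatureTable(
                X=means[label_idx] + noise,
                labels=labels,
                instance_ids=tuple(str(i) for i in range(n_total)),
            )
        )
    return views[0], views[1]


def gen_feature_map_stacks(
    shapes: list[tuple[int, int, int]],
    seed: int = 0,
    constant: float | None = None,
    tags: list[str] | None = None,
) -> list[FeatureMapStack]:
    """Seeded random (or constant-fill) activation stacks for fusion tests."""
    rng = np.random.default_rng(seed)
    tags = tags or [f"layer{i}" for i in range(len(shapes))]
    if len(tags) != len(shapes):
        raise ValueError("one tag per requested shape")
    stacks = []
    for (h, w, c), tag in zip(shapes, tags):
        if constant is not None:
            values = np.full((h, w, c), float(constant))
        else:
            values = rng.normal(size=(h, w, c))
        stacks.append(FeatureMapStack(values=values, source_tag=tag))
    return stacks


def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("svnsfuse.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, index_col=0)


def worked_example() -> tuple[ScoreMatrix, ScoreMatrix, np.ndarray]:
    """The packaged eight-image worked example.

    Returns the TRUE and FALSE score matrices (8 instances x 8 classes,
    alphabetical class order) and the ground-truth labels.  The example
    covers every resolution branch: single-bit agreement, all-zero
    code-words, and multi-bit conflicts.
    """
    t_frame = _load_packaged_csv("worked_example_true.csv")
    f_frame = _load_packaged_csv("worked_example_false.csv")
    truth = _load_packaged_csv("worked_example_truth.csv")["label"].to_numpy()
    ids = tuple(str(i) for i in t_frame.index)
    true_scores = ScoreMatrix(
        values=t_frame.to_numpy(dtype=float),
        polarity=Polarity.TRUE,
        class_order=tuple(t_frame.columns),
        instance_ids=ids,
    )
    false_scores = ScoreMatrix(
        values=f_frame.to_numpy(dtype=float),
        polarity=Polarity.FALSE,
        class_order=tuple(f_frame.columns),
        instance_ids=ids,
    )
    return true_scores, false_scores, truth


def gen_imbalanced_inventory(
    profile: dict[str, int] | None = None, noise: float = 0.0, seed: int = 0
) -> ClassInventory:
    """Class inventory matching a rich/poor profile.

    With ``noise`` = 0 the profile counts (default: the ISIC 2019 inventory)
    are returned exactly; otherwise each count is perturbed by a relative
    Gaussian factor of scale ``noise`` (floored at 1 instance).
    """
    profile = dict(profile) if profile is not None else dict(ISIC_2019_COUNTS)
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if noise == 0:
        return ClassInventory(profile)
    rng = np.random.default_rng(seed)
    counts = {
        label: max(1, int(round(n * (1.0 + noise * rng.normal()))))
        for label, n in profile.items()
    }
    return ClassInventory(counts)
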