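"""Error-correcting output codes: coding matrices and binary-learner ensembles.

Multiclass classification is reduced to binary problems by a classes x
learners coding matrix over {-1, 0, +1}: per column, +1 classes form the
positive training set, -1 classes the negative set, and 0 classes are
discarded entirely.  Three schemes are provided:

``ovo``
    one-versus-one, n(n-1)/2 columns, each pitting one ordered class pair
    against each other.
``ova_true``
    one-versus-all with +1 on the diagonal: learner k is trained to fire on
    class k.  Decoded by *highest* similarity score.
``ova_false``
    the elementwise negation: learner k is trained to fire on everything
    *except* class k.  Decoded by *lowest* similarity score.

Each column is fitted with a soft-margin SVM whose decision values are
mapped to [0, 1] by Platt-style sigmoid calibration, so the per-class
similarity scores are probability-like and can feed the neutrosophic
characterization directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from itertools import combinations

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .svns import Polarity, ScoreMatrix
from .tables import FeatureTable

__all__ = [
    "CodingScheme",
    "CodingMatrix",
    "EnsembleConfig",
    "BinaryLearnerEnsemble",
    "build_ovo_coding",
    "build_ova_coding",
    "train_ensemble",
    "score_classes",
    "decode_true",
    "decode_false",
]

BUNDLE_FORMAT_VERSION = 1


class CodingScheme(str, enum.Enum):
    OVO = "ovo"
    OVA_TRUE = "ova_true"
    OVA_FALSE = "ova_false"


@dataclass(frozen=True)
class CodingMatrix:
    """Classes x learners design over {-1, 0, +1}."""

    entries: np.ndarray
    scheme: CodingScheme
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int8)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "scheme", CodingScheme(self.scheme))
        order = tuple(str(c) for c in self.class_order)
        object.__setattr__(self, "class_order", order)
        if entries.ndim != 2 or entries.shape[0] != len(order):
            raise ValueError("coding matrix rows must match class_order")
        if not np.isin(entries, (-1, 0, 1)).all():
            raise ValueError("coding matrix entries must be in {-1, 0, +1}")
        for j in range(entries.shape[1]):
            col = entries[:, j]
            if not ((col == 1).any() and (col == -1).any()):
                raise ValueError(f"column {j} lacks a positive or negative class")
        if np.any(np.all(entries == 0, axis=1)):
            raise ValueError("coding matrix has an all-zero row")
        if len({tuple(entries[:, j]) for j in range(entries.shape[1])}) != entries.shape[1]:
            raise ValueError("coding matrix has duplicate columns")

    @property
    def n_classes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_learners(self) -> int:
        return self.entries.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=list(self.class_order),
            columns=[f"L{j + 1}" for j in range(self.n_learners)],
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("class").to_csv(path)


def _default_class_order(n: int, class_order=None) -> tuple[str, ...]:
    if class_order is not None:
        order = tuple(str(c) for c in class_order)
        if len(order) != n:
            raise ValueError(f"class_order names {len(order)} classes, expected {n}")
        return order
    return tuple(f"C{j + 1}" for j in range(n))


def build_ovo_coding(n_classes: int, class_order=None) -> CodingMatrix:
    """One-versus-one coding: one column per ordered pair (j, j'), j < j'.

    Columns are enumerated lexicographically; class j takes +1, class j'
    takes -1, every other class is discarded for that learner.
    """
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    pairs = list(combinations(range(n_classes), 2))
    entries = np.zeros((n_classes, len(pairs)), dtype=np.int8)
    for col, (j, jp) in enumerate(pairs):
        entries[j, col] = 1
        entries[jp, col] = -1
    return CodingMatrix(entries, CodingScheme.OVO, _default_class_order(n_classes, class_order))


def build_ova_coding(
    n_classes: int, polarity: Polarity | str = Polarity.TRUE, class_order=None
) -> CodingMatrix:
    """One-versus-all coding: +1 diagonal (true) or its negation (false)."""
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    polarity = Polarity(polarity)
    entries = np.full((n_classes, n_classes), -1, dtype=np.int8)
    np.fill_diagonal(entries, 1)
    if polarity is Polarity.FALSE:
        entries = -entries
    scheme = CodingScheme.OVA_TRUE if polarity is Polarity.TRUE else CodingScheme.OVA_FALSE
    return CodingMatrix(entries, scheme, _default_class_order(n_classes, class_order))


@dataclass(frozen=True)
class EnsembleConfig:
    """Training configuration for the per-column binary SVMs.

    ``calibration_folds`` controls the internal cross-validation used to fit
    the sigmoid map from decision value to [0, 1]; folds are stratified and
    unshuffled so training is deterministic for a given seed.
    """

    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: str | None = None
    calibration_folds: int = 3
    seed: int = 0


@dataclass(frozen=True)
class BinaryLearnerEnsemble:
    """One calibrated binary SVM per coding-matrix column."""

    coding: CodingMatrix
    learners: tuple
    config: EnsembleConfig
    n_features: int

    def __post_init__(self) -> None:
        if len(self.learners) != self.coding.n_learners:
            raise ValueError("learner count does not match coding columns")

    @property
    def polarity(self) -> Polarity:
        return (
            Polarity.FALSE if self.coding.scheme is CodingScheme.OVA_FALSE else Polarity.TRUE
        )

    def save(self, path) -> None:
        """Serialize to a versioned joblib bundle with a config snapshot."""
        joblib.dump(
            {
                "format_version": BUNDLE_FORMAT_VERSION,
                "config": asdict(self.config),
                "scheme": self.coding.scheme.value,
                "class_order": list(self.coding.class_order),
                "entries": self.coding.entries,
                "learners": self.learners,
                "n_features": self.n_features,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "BinaryLearnerEnsemble":
        bundle = joblib.load(path)
        if bundle.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError(f"unsupported bundle format: {bundle.get('format_version')!r}")
        coding = CodingMatrix(
            bundle["entries"], CodingScheme(bundle["scheme"]), tuple(bundle["class_order"])
        )
        return cls(
            coding=coding,
            learners=tuple(bundle["learners"]),
            config=EnsembleConfig(**bundle["config"]),
            n_features=int(bundle["n_features"]),
        )


def _make_learner(config: EnsembleConfig) -> CalibratedClassifierCV:
    svm = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    return CalibratedClassifierCV(svm, method="sigmoid", cv=config.calibration_folds)


def train_ensemble(
    features: FeatureTable,
    coding: CodingMatrix,
    config: EnsembleConfig | None = None,
) -> BinaryLearnerEnsemble:
    """Fit one calibrated binary SVM per coding column.

    Per column, instances of +1 classes form the positive set and -1 classes
    the negative set; 0-coded classes are filtered out before fitting (never
    merely zero-weighted).  Raises if the table carries labels outside the
    coding's class order, or if any column ends up with an empty side.
    """
    if features.labels is None:
        raise ValueError("training requires a labeled feature table")
    config = config or EnsembleConfig()
    order = coding.class_order
    unknown = set(map(str, features.labels)) - set(order)
    if unknown:
        raise ValueError(f"labels not in coding class_order: {sorted(unknown)}")
    class_index = {c: k for k, c in enumerate(order)}
    y_idx = np.array([class_index[str(label)] for label in features.labels])

    learners = []
    for j in range(coding.n_learners):
        codes = coding.entries[y_idx, j]
        mask = codes != 0
        if not (codes == 1).any():
            raise ValueError(f"column {j} has an empty positive set")
        if not (codes == -1).any():
            raise ValueError(f"column {j} has an empty negative set")
        learner = _make_learner(config)
        learner.fit(features.X[mask], codes[mask])
        learners.append(learner)
    return BinaryLearnerEnsemble(
        coding=coding,
        learners=tuple(learners),
        config=config,
        n_features=features.n_features,
    )


def _positive_probabilities(ensemble: BinaryLearnerEnsemble, X: np.ndarray) -> np.ndarray:
    probs = np.empty((X.shape[0], len(ensemble.learners)))
    for j, learner in enumerate(ensemble.learners):
        pos = list(learner.classes_).index(1)
        probs[:, j] = learner.predict_proba(X)[:, pos]
    return probs


def score_classes(ensemble: BinaryLearnerEnsemble, features: FeatureTable) -> ScoreMatrix:
    """Per-class similarity scores in [0, 1].

    For one-versus-all schemes the score of class k is the calibrated
    positive membership of column k's learner.  For one-versus-one, each
    class aggregates the probability mass its columns assign to it (p where
    the class is coded +1, 1 - p where -1), averaged over its columns.
    """
    if features.n_features != ensemble.n_features:
        raise ValueError(
            f"feature dimension {features.n_features} does not match "
            f"training dimension {ensemble.n_features}"
        )
    probs = _positive_probabilities(ensemble, features.X)
    if ensemble.coding.scheme is CodingScheme.OVO:
        entries = ensemble.coding.entries
        scores = np.empty((features.n_instances, ensemble.coding.n_classes))
        for k in range(ensemble.coding.n_classes):
            cols = np.flatnonzero(entries[k] != 0)
            aligned = np.where(entries[k, cols] == 1, probs[:, cols], 1.0 - probs[:, cols])
            scores[:, k] = aligned.mean(axis=1)
    else:
        scores = probs
    return ScoreMatrix(
        values=np.clip(scores, 0.0, 1.0),
        polarity=ensemble.polarity,
        class_order=ensemble.coding.class_order,
        instance_ids=features.instance_ids,
    )


def decode_true(scores: ScoreMatrix) -> np.ndarray:
    """Highest-similarity decoding (argmax per row, lowest-index ties)."""
    idx = np.argmax(scores.values, axis=1)
    return np.array([scores.class_order[k] for k in idx])


def decode_false(scores: ScoreMatrix) -> np.ndarray:
    """Lowest-similarity decoding (argmin per row, lowest-index ties)."""
    idx = np.argmin(scores.values, axis=1)
    return np.array([scores.class_order[k] for k in idx])
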