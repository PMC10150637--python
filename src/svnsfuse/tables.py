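"""Labeled feature tables: the delimited-text interchange format.

A feature table is a CSV with an ``instance`` id column, numeric feature
columns, and (optionally) a trailing ``label`` column.  In memory it is a
thin dataclass over numpy arrays so the classifier stack never touches
pandas directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class FeatureTable:
    """Instances x features matrix with optional labels and instance ids."""

    X: np.ndarray
    labels: np.ndarray | None = None
    instance_ids: tuple[str, ...] = field(default=())
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        if not np.all(np.isfinite(X)):
            raise ValueError("feature table contains non-finite values")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape[0] != X.shape[0]:
                raise ValueError("labels length does not match instance count")
            object.__setattr__(self, "labels", labels)
        ids = tuple(str(i) for i in self.instance_ids) or tuple(
            str(i) for i in range(X.shape[0])
        )
        if len(ids) != X.shape[0]:
            raise ValueError("instance_ids length does not match instance count")
        object.__setattr__(self, "instance_ids", ids)
        names = tuple(self.feature_names) or tuple(f"f{j}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length does not match feature count")
        object.__setattr__(self, "feature_names", names)

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.X, index=list(self.instance_ids), columns=list(self.feature_names)
        )
        if self.labels is not None:
            frame[LABEL_COLUMN] = self.labels
        return frame.rename_axis("instance")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, index_col=0)
        labels = None
        if LABEL_COLUMN in frame.columns:
            labels = frame.pop(LABEL_COLUMN).to_numpy()
        return cls(
            X=frame.to_numpy(dtype=float),
            labels=labels,
            instance_ids=tuple(str(i) for i in frame.index),
            feature_names=tuple(frame.columns),
        )

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X[idx],
            labels=None if self.labels is None else self.labels[idx],
            instance_ids=tuple(self.instance_ids[i] for i in idx),
            feature_names=self.feature_names,
        )
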