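"""Single-valued neutrosophic set (SVNS) characterization and ambiguity resolution.

A pair of opposed classifier ensembles scores every instance against every
class: the *true* ensemble emits a membership T (high for the predicted
class), the *false* ensemble a non-membership F (low for the predicted
class).  Wherever the two disagree an ambiguity zone opens up, quantified by
the indeterminacy membership

    I = 1 - |T - F|

so that (T, I, F) forms a single-valued neutrosophic triple with
0 <= T + I + F <= 3.  A per-class code-word bit CW is set when T strictly
exceeds F, and a crisp scalarization

    CR = (2 + T - I - F) / 3

ranks classes when several bits conflict.  Resolution proceeds per instance:

* exactly one bit set  -> that class (no ambiguity);
* no bit set           -> the class of maximal indeterminacy;
* two or more bits set -> the bit-set class of maximal crisp value.

Ties are broken toward the lowest class index, and a tie T == F clears the
bit, routing the instance to the indeterminacy branch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Polarity",
    "ResolutionMode",
    "ScoreMatrix",
    "SVNSTable",
    "ResolvedPrediction",
    "indeterminacy",
    "crisp_value",
    "codeword_bits",
    "characterize",
    "resolve_ambiguity",
    "classify",
    "CRISP_PLACEHOLDER",
]

#: Crisp value reported for classes whose code-word bit is 0.  With T <= F
#: the crisp formula can only fall below 1/3, so the placeholder never
#: outranks a genuinely bit-set class.
CRISP_PLACEHOLDER = 1.0 / 3.0


class Polarity(str, enum.Enum):
    """Which ensemble produced a score matrix."""

    TRUE = "true"
    FALSE = "false"


class ResolutionMode(str, enum.Enum):
    """Which resolution branch decided an instance."""

    SINGLE_BIT = "single_bit"
    MAX_INDETERMINACY = "max_indeterminacy"
    MAX_CRISP = "max_crisp"


def _check_unit_interval(values: np.ndarray, name: str) -> None:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.asarray(values).ravel()
        offender = bad[~np.isfinite(bad)][0]
        raise ValueError(f"{name} contains non-finite value {offender!r}")
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        flat = values.ravel()
        offender = flat[(flat < 0.0) | (flat > 1.0)][0]
        raise ValueError(f"{name} contains out-of-range value {offender!r}; expected [0, 1]")


@dataclass(frozen=True)
class ScoreMatrix:
    """Instances x classes similarity scores in [0, 1] from one ensemble.

    Parameters
    ----------
    values
        2-D array, rows are instances and columns follow ``class_order``.
    polarity
        ``Polarity.TRUE`` for the true (membership) ensemble,
        ``Polarity.FALSE`` for the false (non-membership) ensemble.
    class_order
        Unique class labels naming the columns.
    instance_ids
        Optional row identifiers; defaults to ``0..n-1`` as strings.
    """

    values: np.ndarray
    polarity: Polarity
    class_order: tuple[str, ...]
    instance_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        order = tuple(str(c) for c in self.class_order)
        if len(set(order)) != len(order):
            raise ValueError("class_order entries must be unique")
        object.__setattr__(self, "class_order", order)
        if values.ndim != 2 or values.shape[1] != len(order):
            raise ValueError(
                f"score matrix has {values.shape[1] if values.ndim == 2 else '?'} columns "
                f"but class_order names {len(order)} classes"
            )
        _check_unit_interval(values, "score matrix")
        ids = tuple(str(i) for i in self.instance_ids) or tuple(
            str(i) for i in range(values.shape[0])
        )
        if len(ids) != values.shape[0]:
            raise ValueError("instance_ids length does not match row count")
        object.__setattr__(self, "instance_ids", ids)

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.instance_ids), columns=list(self.class_order)
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("instance").to_csv(path)

    @classmethod
    def from_csv(cls, path, polarity: Polarity | str) -> "ScoreMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            values=frame.to_numpy(dtype=float),
            polarity=Polarity(polarity),
            class_order=tuple(frame.columns),
            instance_ids=tuple(str(i) for i in frame.index),
        )


@dataclass(frozen=True)
class SVNSTable:
    """Per (instance, class) neutrosophic quintuple (T, I, F, CW, CR)."""

    truth: np.ndarray
    indeterminacy: np.ndarray
    falsity: np.ndarray
    codeword: np.ndarray
    crisp: np.ndarray
    class_order: tuple[str, ...]
    instance_ids: tuple[str, ...]

    @property
    def n_instances(self) -> int:
        return self.truth.shape[0]

    def row(self, i: int) -> "SVNSTable":
        """Single-instance slice (still a table, with one row)."""
        sl = slice(i, i + 1)
        return SVNSTable(
            self.truth[sl],
            self.indeterminacy[sl],
            self.falsity[sl],
            self.codeword[sl],
            self.crisp[sl],
            self.class_order,
            self.instance_ids[i : i + 1],
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (instance, class)."""
        n, k = self.truth.shape
        return pd.DataFrame(
            {
                "instance": np.repeat(list(self.instance_ids), k),
                "class": list(self.class_order) * n,
                "T": self.truth.ravel(),
                "I": self.indeterminacy.ravel(),
                "F": self.falsity.ravel(),
                "CW": self.codeword.ravel(),
                "CR": self.crisp.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ResolvedPrediction:
    """Final class call for one instance plus the branch that produced it."""

    instance_id: str
    label: str
    mode: ResolutionMode


def indeterminacy(t, f):
    """Indeterminacy membership ``I = 1 - |T - F|``.

    Accepts scalars or matched arrays in [0, 1]; the closer the true and
    false memberships are, the larger the ambiguity.
    """
    t_arr = np.asarray(t, dtype=float)
    f_arr = np.asarray(f, dtype=float)
    if t_arr.shape != f_arr.shape:
        raise ValueError(f"shape mismatch: {t_arr.shape} vs {f_arr.shape}")
    _check_unit_interval(t_arr, "truth membership")
    _check_unit_interval(f_arr, "falsity membership")
    out = 1.0 - np.abs(t_arr - f_arr)
    return float(out) if np.isscalar(t) and np.isscalar(f) else out


def crisp_value(t, i, f):
    """Crisp scalarization ``CR = (2 + T - I - F) / 3``.

    Where the bit condition T > F holds this equals ``(1 + 2(T - F)) / 3``
    and lies in (1/3, 1]; with T == F (hence I == 1) it collapses to 1/3.
    """
    for name, x in (("truth", t), ("indeterminacy", i), ("falsity", f)):
        _check_unit_interval(np.asarray(x, dtype=float), f"{name} membership")
    out = (2.0 + np.asarray(t, float) - np.asarray(i, float) - np.asarray(f, float)) / 3.0
    return float(out) if np.isscalar(t) else out


def codeword_bits(t_row, f_row) -> np.ndarray:
    """Per-class bits: 1 where the true score strictly exceeds the false score.

    Ties (T == F) yield 0, deliberately routing full-agreement-of-ambiguity
    cases to the indeterminacy branch of the resolver.
    """
    t_arr = np.asarray(t_row, dtype=float)
    f_arr = np.asarray(f_row, dtype=float)
    if t_arr.shape != f_arr.shape:
        raise ValueError(f"shape mismatch: {t_arr.shape} vs {f_arr.shape}")
    return (t_arr > f_arr).astype(np.int8)


def characterize(true_scores: ScoreMatrix, false_scores: ScoreMatrix) -> SVNSTable:
    """Build the full SVNS table from paired true/false score matrices.

    The crisp value is computed only where the code-word bit is set; other
    cells carry the 1/3 placeholder (the formula cannot exceed 1/3 there, so
    reporting the constant keeps the table easy to read without affecting
    resolution).
    """
    if true_scores.polarity is not Polarity.TRUE or false_scores.polarity is not Polarity.FALSE:
        raise ValueError(
            "characterize needs a true-polarity and a false-polarity matrix, got "
            f"{true_scores.polarity.value!r} and {false_scores.polarity.value!r}"
        )
    if true_scores.class_order != false_scores.class_order:
        raise ValueError("class_order of true and false matrices differ")
    if true_scores.values.shape != false_scores.values.shape:
        raise ValueError(
            f"shape mismatch: {true_scores.values.shape} vs {false_scores.values.shape}"
        )
    t = true_scores.values
    f = false_scores.values
    ind = 1.0 - np.abs(t - f)
    cw = (t > f).astype(np.int8)
    cr = np.full_like(t, CRISP_PLACEHOLDER)
    mask = cw == 1
    cr[mask] = (2.0 + t[mask] - ind[mask] - f[mask]) / 3.0
    return SVNSTable(
        truth=t,
        indeterminacy=ind,
        falsity=f,
        codeword=cw,
        crisp=cr,
        class_order=true_scores.class_order,
        instance_ids=true_scores.instance_ids,
    )


def resolve_ambiguity(row: SVNSTable) -> ResolvedPrediction:
    """Resolve a single instance: single bit, max-I, or max-CR branch."""
    if row.n_instances != 1:
        raise ValueError("resolve_ambiguity expects a single-instance slice")
    bits = row.codeword[0]
    n_set = int(bits.sum())
    if n_set == 1:
        k = int(np.argmax(bits))
        mode = ResolutionMode.SINGLE_BIT
    elif n_set == 0:
        k = int(np.argmax(row.indeterminacy[0]))
        mode = ResolutionMode.MAX_INDETERMINACY
    else:
        crisp = np.where(bits == 1, row.crisp[0], -np.inf)
        k = int(np.argmax(crisp))
        mode = ResolutionMode.MAX_CRISP
    return ResolvedPrediction(
        instance_id=row.instance_ids[0], label=row.class_order[k], mode=mode
    )


def classify(
    true_scores: ScoreMatrix, false_scores: ScoreMatrix
) -> list[ResolvedPrediction]:
    """Characterize then resolve every instance; deterministic."""
    table = characterize(true_scores, false_scores)
    return [resolve_ambiguity(table.row(i)) for i in range(table.n_instances)]


def predictions_to_frame(predictions: Sequence[ResolvedPrediction]) -> pd.DataFrame:
    """Tabulate resolved predictions (instance, label, resolution mode)."""
    return pd.DataFrame(
        {
            "instance": [p.instance_id for p in predictions],
            "label": [p.label for p in predictions],
            "mode": [p.mode.value for p in predictions],
        }
    )
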