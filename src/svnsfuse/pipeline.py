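"""End-to-end orchestration of the two-view neutrosophic fusion pipeline.

The full method: train a *true* one-vs-all ensemble on view A and a *false*
one-vs-all ensemble on view B (two different feature representations of the
same instances), score held-out instances with both, characterize each
(instance, class) pair as a neutrosophic (T, I, F) triple, and resolve
contradictions between the two ensembles to obtain the final class call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ecoc, metrics, svns
from .svns import Polarity
from .synthetic import SyntheticSpec, gen_two_view_features
from .tables import FeatureTable

__all__ = [
    "TrueFalseModel",
    "stratified_split",
    "train_true_false",
    "predict_true_false",
    "evaluate_predictions",
    "run_synthetic_pipeline",
]


@dataclass(frozen=True)
class TrueFalseModel:
    """Paired true/false ensembles sharing one class order."""

    true_ensemble: ecoc.BinaryLearnerEnsemble
    false_ensemble: ecoc.BinaryLearnerEnsemble

    def __post_init__(self) -> None:
        if (
            self.true_ensemble.coding.class_order
            != self.false_ensemble.coding.class_order
        ):
            raise ValueError("true and false ensembles disagree on class order")

    @property
    def class_order(self) -> tuple[str, ...]:
        return self.true_ensemble.coding.class_order


def stratified_split(
    table: FeatureTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays for a per-class train/validation/test split.

    Fractions must sum to 1; instances of each class are shuffled with the
    seed and cut at the stated proportions, so all three parts keep the
    class balance of the input.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if table.labels is None:
        raise ValueError("stratified split requires labels")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for label in np.unique(table.labels):
        idx = np.flatnonzero(table.labels == label)
        rng.shuffle(idx)
        n = idx.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train.extend(idx[:n_train])
        val.extend(idx[n_train : n_train + n_val])
        test.extend(idx[n_train + n_val :])
    return np.sort(train), np.sort(val), np.sort(test)


def _check_aligned(view_a: FeatureTable, view_b: FeatureTable) -> None:
    if view_a.labels is None or view_b.labels is None:
        raise ValueError("both views must be labeled")
    if view_a.n_instances != view_b.n_instances:
        raise ValueError(
            f"views differ in instance count: {view_a.n_instances} vs {view_b.n_instances}"
        )
    if not np.array_equal(
        np.asarray(view_a.labels, dtype=str), np.asarray(view_b.labels, dtype=str)
    ):
        raise ValueError("views carry different labels for the same instances")


def train_true_false(
    view_a: FeatureTable,
    view_b: FeatureTable,
    class_order=None,
    config: ecoc.EnsembleConfig | None = None,
) -> TrueFalseModel:
    """Train the true ensemble on view A and the false ensemble on view B."""
    _check_aligned(view_a, view_b)
    if class_order is None:
        class_order = tuple(sorted(np.unique(np.asarray(view_a.labels, dtype=str))))
    n = len(class_order)
    coding_true = ecoc.build_ova_coding(n, Polarity.TRUE, class_order)
    coding_false = ecoc.build_ova_coding(n, Polarity.FALSE, class_order)
    return TrueFalseModel(
        true_ensemble=ecoc.train_ensemble(view_a, coding_true, config),
        false_ensemble=ecoc.train_ensemble(view_b, coding_false, config),
    )


def predict_true_false(
    model: TrueFalseModel, view_a: FeatureTable, view_b: FeatureTable
) -> tuple[svns.SVNSTable, list[svns.ResolvedPrediction]]:
    """Score both views, characterize, and resolve every instance."""
    true_scores = ecoc.score_classes(model.true_ensemble, view_a)
    false_scores = ecoc.score_classes(model.false_ensemble, view_b)
    table = svns.characterize(true_scores, false_scores)
    predictions = [svns.resolve_ambiguity(table.row(i)) for i in range(table.n_instances)]
    return table, predictions


def evaluate_predictions(
    predictions, truth, class_order
) -> metrics.MetricsReport:
    """Confusion matrix and per-class/macro metrics for resolved predictions."""
    labels = [p.label if isinstance(p, svns.ResolvedPrediction) else str(p) for p in predictions]
    conf = metrics.confusion(truth, labels, class_order)
    return metrics.macro_report(conf, class_order)


def run_synthetic_pipeline(
    spec: SyntheticSpec,
    config: ecoc.EnsembleConfig | None = None,
    test_fraction: float = 0.2,
) -> metrics.MetricsReport:
    """Generate two-view data, train, and evaluate on a held-out split.

    A convenience wrapper used for parameter-recovery studies: the split is
    stratified, the true ensemble trains on view A and the false ensemble on
    view B, and the returned report scores the neutrosophic resolution on
    the held-out part.
    """
    view_a, view_b = gen_two_view_features(spec)
    train_idx, _, test_idx = stratified_split(
        view_a, (1.0 - test_fraction, 0.0, test_fraction), seed=spec.seed
    )
    config = config or ecoc.EnsembleConfig(seed=spec.seed)
    model = train_true_false(
        view_a.subset(train_idx),
        view_b.subset(train_idx),
        class_order=spec.class_names,
        config=config,
    )
    _, predictions = predict_true_false(
        model, view_a.subset(test_idx), view_b.subset(test_idx)
    )
    truth = np.asarray(view_a.labels)[test_idx]
    return evaluate_predictions(predictions, truth, spec.class_names)
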