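"""Coding-matrix construction and calibrated binary-learner ensembles."""

from itertools import combinations

import numpy as np
import pytest

from svnsfuse import (
    EnsembleConfig,
    FeatureTable,
    Polarity,
    ScoreMatrix,
    build_ova_coding,
    build_ovo_coding,
    decode_false,
    decode_true,
    score_classes,
    train_ensemble,
)
from svnsfuse.ecoc import CodingMatrix, CodingScheme

# Frozen 8-class one-versus-one design: 28 learners, lexicographic pairs.
# Row j holds +1 where class j is the first member of the pair, -1 where
# it is the second, 0 elsewhere.
OVO_8 = [
    [1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [-1, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, -1, 0, 0, 0, 0, 0, -1, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, -1, 0, 0, 0, 0, 0, -1, 0, 0, 0, 0, -1, 0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, -1, 0, 0, 0, 0, 0, -1, 0, 0, 0, 0, -1, 0, 0, 0, -1, 0, 0, 0, 1, 1, 1, 0, 0, 0],
    [0, 0, 0, 0, -1, 0, 0, 0, 0, 0, -1, 0, 0, 0, 0, -1, 0, 0, 0, -1, 0, 0, -1, 0, 0, 1, 1, 0],
    [0, 0, 0, 0, 0, -1, 0, 0, 0, 0, 0, -1, 0, 0, 0, 0, -1, 0, 0, 0, -1, 0, 0, -1, 0, -1, 0, 1],
    [0, 0, 0, 0, 0, 0, -1, 0, 0, 0, 0, 0, -1, 0, 0, 0, 0, -1, 0, 0, 0, -1, 0, 0, -1, 0, -1, -1],
]


def gaussian_table(n_classes=3, per_class=30, d=8, separation=6.0, seed=0):
    rng = np.random.default_rng(seed)
    means = np.zeros((n_classes, d))
    means[np.arange(n_classes), np.arange(n_classes)] = separation
    labels = np.repeat([f"C{j + 1}" for j in range(n_classes)], per_class)
    idx = np.repeat(np.arange(n_classes), per_class)
    X = means[idx] + rng.normal(size=(n_classes * per_class, d))
    return FeatureTable(X=X, labels=labels)


class TestCodingMatrices:
    def test_ovo_8_matches_frozen_design(self):
        coding = build_ovo_coding(8)
        assert coding.entries.tolist() == OVO_8

    def test_ovo_2(self):
        coding = build_ovo_coding(2)
        assert coding.entries.tolist() == [[1], [-1]]

    def test_ovo_5_matches_pair_enumeration(self):
        coding = build_ovo_coding(5)
        assert coding.n_learners == 10
        for col, (j, jp) in enumerate(combinations(range(5), 2)):
            expected = np.zeros(5, dtype=int)
            expected[j], expected[jp] = 1, -1
            assert coding.entries[:, col].tolist() == expected.tolist()

    def test_ova_true_8(self):
        coding = build_ova_coding(8, Polarity.TRUE)
        expected = -np.ones((8, 8), dtype=int)
        np.fill_diagonal(expected, 1)
        assert coding.entries.tolist() == expected.tolist()

    def test_ova_false_is_negation(self):
        true = build_ova_coding(8, Polarity.TRUE)
        false = build_ova_coding(8, Polarity.FALSE)
        assert np.array_equal(false.entries, -true.entries)

    def test_ova_true_3(self):
        coding = build_ova_coding(3, Polarity.TRUE)
        assert coding.entries.tolist() == [[1, -1, -1], [-1, 1, -1], [-1, -1, 1]]

    @pytest.mark.parametrize("n", range(2, 13))
    @pytest.mark.parametrize("builder", [
        build_ovo_coding,
        lambda n: build_ova_coding(n, Polarity.TRUE),
        lambda n: build_ova_coding(n, Polarity.FALSE),
    ])
    def test_invariants_hold_for_all_sizes(self, n, builder):
        coding = builder(n)
        entries = coding.entries
        assert np.isin(entries, (-1, 0, 1)).all()
        # every column has both a positive and a negative class
        assert ((entries == 1).any(axis=0) & (entries == -1).any(axis=0)).all()
        # no all-zero row, no duplicate columns
        assert not np.any(np.all(entries == 0, axis=1))
        cols = {tuple(entries[:, j]) for j in range(entries.shape[1])}
        assert len(cols) == entries.shape[1]
        if coding.scheme is CodingScheme.OVO:
            assert entries.shape[1] == n * (n - 1) // 2
            assert ((entries == 1).sum(axis=0) == 1).all()
            assert ((entries == -1).sum(axis=0) == 1).all()

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            build_ovo_coding(1)
        with pytest.raises(ValueError):
            build_ova_coding(1)

    def test_malformed_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive or negative"):
            CodingMatrix([[1, 1], [0, -1]], CodingScheme.OVA_TRUE, ("a", "b"))
        with pytest.raises(ValueError, match="duplicate"):
            CodingMatrix([[1, 1], [-1, -1]], CodingScheme.OVA_TRUE, ("a", "b"))


class TestTraining:
    def test_separable_true_ensemble_resubstitution(self):
        table = gaussian_table(n_classes=3, per_class=30, seed=1)
        coding = build_ova_coding(3, Polarity.TRUE, ("C1", "C2", "C3"))
        ensemble = train_ensemble(table, coding, EnsembleConfig(seed=1))
        scores = score_classes(ensemble, table)
        assert (decode_true(scores) == table.labels).mean() == 1.0

    def test_separable_false_ensemble_recovers_same_labels(self):
        table = gaussian_table(n_classes=3, per_class=30, seed=1)
        coding = build_ova_coding(3, Polarity.FALSE, ("C1", "C2", "C3"))
        ensemble = train_ensemble(table, coding, EnsembleConfig(seed=1))
        scores = score_classes(ensemble, table)
        assert scores.polarity is Polarity.FALSE
        assert (decode_false(scores) == table.labels).mean() == 1.0

    def test_eight_class_heldout_accuracy(self):
        train = gaussian_table(n_classes=8, per_class=50, d=16, separation=4.0, seed=7)
        test = gaussian_table(n_classes=8, per_class=20, d=16, separation=4.0, seed=8)
        coding = build_ova_coding(8, Polarity.TRUE, tuple(f"C{j+1}" for j in range(8)))
        ensemble = train_ensemble(train, coding, EnsembleConfig(seed=7))
        scores = score_classes(ensemble, test)
        assert (decode_true(scores) == test.labels).mean() >= 0.95

    def test_scores_in_unit_interval_and_argmax_consistency(self):
        table = gaussian_table(n_classes=8, per_class=30, d=16, separation=4.0, seed=3)
        coding = build_ova_coding(8, Polarity.TRUE, tuple(f"C{j+1}" for j in range(8)))
        ensemble = train_ensemble(table, coding, EnsembleConfig(seed=3))
        scores = score_classes(ensemble, table)
        assert scores.values.min() >= 0.0 and scores.values.max() <= 1.0
        # calibrated argmax agrees with the raw decision-value argmax on
        # nearly all training instances
        raw = np.column_stack(
            [clf.calibrated_classifiers_[0].estimator.decision_function(table.X)
             for clf in ensemble.learners]
        )
        agree = (np.argmax(scores.values, axis=1) == np.argmax(raw, axis=1)).mean()
        assert agree >= 0.95

    def test_training_reproducible_with_seed(self):
        table = gaussian_table(n_classes=3, per_class=30, seed=2)
        coding = build_ova_coding(3, Polarity.TRUE, ("C1", "C2", "C3"))
        s1 = score_classes(train_ensemble(table, coding, EnsembleConfig(seed=5)), table)
        s2 = score_classes(train_ensemble(table, coding, EnsembleConfig(seed=5)), table)
        assert np.array_equal(s1.values, s2.values)

    def test_unknown_label_rejected(self):
        table = gaussian_table(n_classes=3, per_class=10, seed=0)
        coding = build_ova_coding(2, Polarity.TRUE, ("C1", "C2"))
        with pytest.raises(ValueError, match="not in coding"):
            train_ensemble(table, coding)

    def test_empty_column_side_named(self):
        # ovo column pairing C1 vs C3 has no C3 instances in this table
        table = gaussian_table(n_classes=2, per_class=10, seed=0)
        coding = build_ovo_coding(3, ("C1", "C2", "C3"))
        with pytest.raises(ValueError, match="column"):
            train_ensemble(table, coding)

    def test_dimension_mismatch_rejected(self):
        table = gaussian_table(n_classes=3, per_class=10, d=8, seed=0)
        coding = build_ova_coding(3, Polarity.TRUE, ("C1", "C2", "C3"))
        ensemble = train_ensemble(table, coding, EnsembleConfig(calibration_folds=2))
        wrong = FeatureTable(np.zeros((2, 5)))
        with pytest.raises(ValueError, match="dimension"):
            score_classes(ensemble, wrong)

    def test_ovo_two_class_scores_complementary(self):
        table = gaussian_table(n_classes=2, per_class=30, seed=4)
        coding = build_ovo_coding(2, ("C1", "C2"))
        ensemble = train_ensemble(table, coding, EnsembleConfig(seed=4))
        scores = score_classes(ensemble, table)
        assert np.allclose(scores.values[:, 0] + scores.values[:, 1], 1.0)

    def test_bundle_roundtrip(self, tmp_path):
        from svnsfuse import BinaryLearnerEnsemble

        table = gaussian_table(n_classes=3, per_class=30, seed=6)
        coding = build_ova_coding(3, Polarity.TRUE, ("C1", "C2", "C3"))
        ensemble = train_ensemble(table, coding, EnsembleConfig(seed=6))
        path = tmp_path / "bundle.joblib"
        ensemble.save(path)
        loaded = BinaryLearnerEnsemble.load(path)
        assert loaded.config == ensemble.config
        assert np.array_equal(
            score_classes(loaded, table).values, score_classes(ensemble, table).values
        )


class TestDecoding:
    def test_one_hot_rows(self):
        order = ("a", "b", "c")
        scores = ScoreMatrix(np.eye(3), Polarity.TRUE, order)
        assert decode_true(scores).tolist() == list(order)
        comp = ScoreMatrix(1 - np.eye(3), Polarity.FALSE, order)
        assert decode_false(comp).tolist() == list(order)

    def test_worked_example_baselines(self, example):
        t, f, truth = example
        assert decode_true(t).tolist() == ["NV", "MEL", "MEL", "NV", "NV", "BCC", "NV", "MEL"]
        assert decode_false(f).tolist() == ["NV", "MEL", "NV", "MEL", "MEL", "SCC", "BKL", "BCC"]
        assert (decode_true(t) == truth).sum() == 3
        assert (decode_false(f) == truth).sum() == 6

    def test_random_rows_match_exhaustive_scan(self, rng):
        values = rng.uniform(size=(40, 6))
        order = tuple(f"C{j}" for j in range(6))
        scores = ScoreMatrix(values, Polarity.TRUE, order)
        for i, label in enumerate(decode_true(scores)):
            assert values[i][order.index(label)] == max(values[i])
        for i, label in enumerate(decode_false(ScoreMatrix(values, Polarity.FALSE, order))):
            assert values[i][order.index(label)] == min(values[i])

    def test_true_and_complement_false_agree(self, rng):
        values = rng.uniform(size=(25, 5))
        order = tuple(f"C{j}" for j in range(5))
        t = decode_true(ScoreMatrix(values, Polarity.TRUE, order))
        f = decode_false(ScoreMatrix(1 - values, Polarity.FALSE, order))
        assert t.tolist() == f.tolist()
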