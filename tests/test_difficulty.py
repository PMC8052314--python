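"""Difficulty labels: exhaustive outcome mapping, metric arithmetic from the
confusion matrix, and the stratified k-fold harness."""

import numpy as np
import pytest

from ampulla.difficulty import (
    BINARY_CLASSES,
    FOUR_CLASSES,
    ClassifierConfig,
    DifficultyLabel,
    OutcomeRecord,
    UndefinedAUCError,
    aggregate_reports,
    evaluate_classifier,
    kfold_harness,
    map_outcome,
    report_from_predictions,
    train_difficulty_classifier,
)

TINY_CLF = ClassifierConfig(input_size=16, backbone="small", max_epochs=2, batch_size=16, seed=0)


class TestMapOutcome:
    @pytest.mark.parametrize(
        "time,technique,success,expected",
        [
            # exhaustive over success x technique x {below, at, above} the 5-min mark
            (130.0, False, True, "easy"),
            (300.0, False, True, "easy"),  # boundary: exactly 5 min is not "exceeded"
            (301.0, False, True, "over_5min"),
            (130.0, True, True, "additional_technique"),
            (300.0, True, True, "additional_technique"),
            (400.0, True, True, "additional_technique"),  # technique beats over_5min
            (None, False, False, "failure"),
            (None, True, False, "failure"),
            (130.0, False, False, "failure"),  # failure beats everything
            (400.0, True, False, "failure"),
            (0.0, False, True, "easy"),
        ],
    )
    def test_truth_table(self, time, technique, success, expected):
        label = map_outcome(OutcomeRecord(time, technique, success))
        assert label.four_class == expected
        assert label.binary == ("easy" if expected == "easy" else "difficult")

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            map_outcome(OutcomeRecord(-1.0, False, True))

    def test_successful_case_requires_a_time(self):
        with pytest.raises(ValueError):
            map_outcome(OutcomeRecord(None, False, True))

    def test_binary_consistency_is_structural(self):
        for c in FOUR_CLASSES:
            lab = DifficultyLabel(c)
            assert (lab.binary == "easy") == (c == "easy")


class TestReports:
    def test_metrics_from_confusion_matrix(self):
        # rows = GT (easy, difficult); 30 easy correct, 10 ->difficult, etc.
        y_true = np.array([0] * 40 + [1] * 20)
        y_pred = np.array([0] * 30 + [1] * 10 + [0] * 10 + [1] * 10)
        rep = report_from_predictions(y_true, y_pred, BINARY_CLASSES)
        assert rep.per_class["easy"]["recall"] == pytest.approx(0.75)
        assert rep.per_class["difficult"]["recall"] == pytest.approx(0.5)
        assert rep.accuracy == pytest.approx(40 / 60)
        np.testing.assert_array_equal(rep.confusion, [[30, 10], [10, 10]])

    def test_f1_is_harmonic_mean_and_macro_is_class_mean(self):
        y_true = np.array([0, 0, 0, 1, 1, 1, 1])
        y_pred = np.array([0, 1, 0, 1, 0, 1, 1])
        rep = report_from_predictions(y_true, y_pred, BINARY_CLASSES)
        for c in BINARY_CLASSES:
            p, r, f = (rep.per_class[c][k] for k in ("precision", "recall", "f1"))
            assert f == pytest.approx(2 * p * r / (p + r))
        assert rep.macro_f1 == pytest.approx(
            np.mean([rep.per_class[c]["f1"] for c in BINARY_CLASSES])
        )

    def test_perfect_predictions_score_one(self):
        y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        rep = report_from_predictions(y, y, FOUR_CLASSES)
        assert rep.accuracy == rep.macro_f1 == rep.macro_recall == 1.0

    def test_single_class_auc_is_undefined(self):
        with pytest.raises(UndefinedAUCError):
            report_from_predictions(
                np.zeros(5, dtype=int), np.zeros(5, dtype=int), BINARY_CLASSES, np.linspace(0, 1, 5)
            )

    def test_metrics_recomputable_from_stored_confusion(self):
        y_true = np.array([0, 0, 1, 1, 1, 0, 1, 0, 0, 1])
        y_pred = np.array([0, 1, 1, 0, 1, 0, 1, 0, 1, 0])
        rep = report_from_predictions(y_true, y_pred, BINARY_CLASSES)
        conf = rep.confusion
        recall_easy = conf[0, 0] / conf[0].sum()
        precision_easy = conf[0, 0] / conf[:, 0].sum()
        assert rep.per_class["easy"]["recall"] == pytest.approx(recall_easy)
        assert rep.per_class["easy"]["precision"] == pytest.approx(precision_easy)
        assert rep.accuracy == pytest.approx(np.trace(conf) / conf.sum())


class TestTraining:
    def test_same_seed_logs_identical(self, small_dataset):
        ds = [(s.image, s.label) for s in small_dataset]
        a = train_difficulty_classifier(ds, "binary", "macro_f1", TINY_CLF)
        b = train_difficulty_classifier(ds, "binary", "macro_f1", TINY_CLF)
        assert a.training_log == b.training_log

    def test_selected_epoch_maximizes_stop_metric(self, small_dataset):
        ds = [(s.image, s.label) for s in small_dataset]
        clf = train_difficulty_classifier(
            ds, "binary", "accuracy",
            ClassifierConfig(input_size=16, max_epochs=4, batch_size=16, seed=1),
        )
        vals = [e["val_accuracy"] for e in clf.training_log]
        assert vals[clf.best_epoch] == max(vals)

    def test_missing_class_rejected(self, small_dataset):
        easy_only = [(s.image, s.label) for s in small_dataset if s.label.four_class == "easy"]
        with pytest.raises(ValueError):
            train_difficulty_classifier(easy_only, "binary", "macro_f1", TINY_CLF)

    def test_unknown_stop_metric_rejected(self, small_dataset):
        ds = [(s.image, s.label) for s in small_dataset]
        with pytest.raises(ValueError):
            train_difficulty_classifier(ds, "binary", "auc", TINY_CLF)


class TestKFold:
    def test_partition_is_disjoint_exhaustive_and_stratified(self, small_dataset):
        ds = [(s.image, s.label) for s in small_dataset]
        result = kfold_harness(ds, task="binary", config=TINY_CLF, k=3, seed=5)
        folds = result["fold_indices"]
        flat = sorted(i for fold in folds for i in fold)
        assert flat == list(range(len(ds)))  # exhaustive and disjoint
        overall = np.mean([lab.binary == "difficult" for _, lab in ds])
        for fold in folds:
            frac = np.mean([ds[i][1].binary == "difficult" for i in fold])
            assert abs(frac * len(fold) - overall * len(fold)) <= 1.5  # ±1 sample
        # aggregate mean equals the mean of per-fold accuracies
        assert result["mean"]["accuracy"] == pytest.approx(
            np.mean([r.accuracy for r in result["folds"]])
        )

    def test_k_larger_than_dataset_rejected(self, small_dataset):
        ds = [(s.image, s.label) for s in small_dataset[:4]]
        with pytest.raises(ValueError):
            kfold_harness(ds, config=TINY_CLF, k=10)

    def test_aggregate_uses_population_sd(self):
        reps = [
            report_from_predictions(np.array([0, 1]), np.array([0, 1]), BINARY_CLASSES),
            report_from_predictions(np.array([0, 1]), np.array([0, 0]), BINARY_CLASSES),
        ]
        agg = aggregate_reports(reps)
        assert agg["mean"]["accuracy"] == pytest.approx(0.75)
        assert agg["sd"]["accuracy"] == pytest.approx(0.25)  # ddof=0
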