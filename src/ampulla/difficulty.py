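"""Cannulation-difficulty labels, classifiers and cross-validated evaluation.

Procedural outcomes (cannulation time, use of additional cannulation
techniques, success) are mapped to difficulty labels:

* binary: *easy* vs *difficult*, where a case is difficult when the
  cannulation time exceeded 5 minutes, additional techniques were used, or
  the cannulation failed;
* four-class: *easy*, *over_5min* (time > 300 s), *additional_technique*,
  *failure*, with precedence failure > additional_technique > over_5min >
  easy (in practice every additional-technique case also exceeds 5 minutes,
  so the precedence only resolves that overlap).

A small convolutional classifier predicts these labels from the endoscopic
image alone; evaluation reports per-class precision/recall/F1, accuracy,
binary AUC and macro averages, aggregated as mean ± population sd over
stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .detector import DetectorConfig, _augmented_batch, _prepare, _state_dict, _load_state
from .geometry import BBox

__all__ = [
    "FIVE_MINUTES_S",
    "BINARY_CLASSES",
    "FOUR_CLASSES",
    "OutcomeRecord",
    "DifficultyLabel",
    "ClassifierConfig",
    "ClassifierReport",
    "TrainedClassifier",
    "UndefinedAUCError",
    "map_outcome",
    "train_difficulty_classifier",
    "predict_proba",
    "evaluate_classifier",
    "kfold_harness",
    "aggregate_reports",
]

FIVE_MINUTES_S = 300.0
BINARY_CLASSES = ("easy", "difficult")
FOUR_CLASSES = ("easy", "over_5min", "additional_technique", "failure")

#: Named backbone presets: (base_channels, depth).  The names mirror the
#: families commonly used for this task; here they select width/depth of the
#: from-scratch CNN.
BACKBONE_PRESETS = {
    "small": (8, 3),
    "vgg": (12, 3),
    "resnet": (16, 3),
    "densenet": (16, 4),
}


class UndefinedAUCError(ValueError):
    """AUC is undefined when the evaluation set contains a single class."""


@dataclass(frozen=True)
class OutcomeRecord:
    """Procedural outcome of one cannulation attempt.

    ``cannulation_time_s`` is the time from approaching the ampulla to deep
    cannulation of the common bile duct; it is absent (None) when the
    cannulation failed.
    """

    cannulation_time_s: float | None
    additional_technique: bool
    success: bool


@dataclass(frozen=True)
class DifficultyLabel:
    four_class: str

    def __post_init__(self) -> None:
        if self.four_class not in FOUR_CLASSES:
            raise ValueError(f"unknown class {self.four_class!r}")

    @property
    def binary(self) -> str:
        return "easy" if self.four_class == "easy" else "difficult"


def map_outcome(rec: OutcomeRecord) -> DifficultyLabel:
    """Map an outcome record to its difficulty label.

    Precedence: failure > additional_technique > over_5min ("exceeded 5
    minutes" is strict, time > 300 s) > easy.  A failed cannulation maps to
    the failure class regardless of time or technique flags.
    """
    if rec.cannulation_time_s is not None and rec.cannulation_time_s < 0:
        raise ValueError("cannulation time must be nonnegative")
    if not rec.success:
        return DifficultyLabel("failure")
    if rec.cannulation_time_s is None:
        raise ValueError("a successful cannulation must record its time")
    if rec.additional_technique:
        return DifficultyLabel("additional_technique")
    if rec.cannulation_time_s > FIVE_MINUTES_S:
        return DifficultyLabel("over_5min")
    return DifficultyLabel("easy")


@dataclass
class ClassifierConfig:
    """Training configuration for the difficulty classifier."""

    input_size: int = 32
    backbone: str = "small"
    learning_rate: float = 1e-2
    max_epochs: int = 40
    early_stop_patience: int = 12
    batch_size: int = 32
    val_fraction: float = 0.2
    seed: int = 0
    augmentation: tuple[str, ...] = ("hflip", "vflip", "shear", "rotate")

    def base_depth(self) -> tuple[int, int]:
        if self.backbone not in BACKBONE_PRESETS:
            raise ValueError(f"unknown backbone preset {self.backbone!r}")
        return BACKBONE_PRESETS[self.backbone]


class ConvClassifier:
    """Conv-ReLU-pool stages followed by a flattened linear softmax head.

    The flattened head keeps spatial information, which matters here: some
    difficulty cues are thin local structures (the crease stripe) that a
    global average pool would wash out.
    """

    def __init__(
        self, n_classes: int, input_size: int = 32, base: int = 8, depth: int = 3, seed: int = 0
    ) -> None:
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        ch = 3
        for d in range(depth):
            out = base * 2**d
            layers += [nn.Conv2d(ch, out, rng=rng), nn.ReLU(), nn.MaxPool2d()]
            ch = out
        self.body = nn.Sequential(*layers)
        spatial = input_size // 2**depth
        self._feat_shape = (ch, spatial, spatial)
        self.fc = nn.Linear(ch * spatial * spatial, n_classes, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        feat = self.body.forward(x)
        return self.fc.forward(feat.reshape(feat.shape[0], -1))

    def backward(self, dy: np.ndarray) -> None:
        dflat = self.fc.backward(dy)
        self.body.backward(dflat.reshape((dflat.shape[0],) + self._feat_shape))

    def layers(self) -> list[nn.Layer]:
        return list(self.body.iter_layers()) + [self.fc]


@dataclass
class TrainedClassifier:
    model: ConvClassifier
    config: ClassifierConfig
    task: str  # "binary" or "four_class"
    classes: tuple[str, ...]
    training_log: list[dict]
    best_epoch: int = 0


def _classes_for(task: str) -> tuple[str, ...]:
    if task == "binary":
        return BINARY_CLASSES
    if task == "four_class":
        return FOUR_CLASSES
    raise ValueError(f"unknown task {task!r}")


def _label_indices(labels: Sequence[DifficultyLabel], task: str) -> np.ndarray:
    classes = _classes_for(task)
    names = [lab.binary if task == "binary" else lab.four_class for lab in labels]
    return np.array([classes.index(n) for n in names], dtype=np.int64)


def train_difficulty_classifier(
    dataset: Sequence[tuple[np.ndarray, DifficultyLabel]],
    task: str = "binary",
    stop_metric: str = "macro_f1",
    config: ClassifierConfig | None = None,
) -> TrainedClassifier:
    """Train a difficulty classifier with augmentation and early stopping.

    ``stop_metric`` selects the validation quantity that drives early
    stopping and epoch selection: ``"macro_f1"`` (unweighted mean of the
    per-class F1 scores) or ``"accuracy"``.
    """
    config = config or ClassifierConfig()
    if stop_metric not in ("macro_f1", "accuracy"):
        raise ValueError(f"unknown stop_metric {stop_metric!r}")
    classes = _classes_for(task)
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    labels = _label_indices([lab for _, lab in dataset], task)
    counts = np.bincount(labels, minlength=len(classes))
    if (counts < 2).any():
        missing = [classes[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"each class needs at least 2 training samples; short: {missing}")

    size = config.input_size
    images, _ = _prepare([(img, BBox(0, 0, 1, 1)) for img, _ in dataset], size)
    tr, va = train_test_split(
        np.arange(len(labels)),
        test_size=config.val_fraction,
        random_state=config.seed,
        stratify=labels,
    )
    base, depth = config.base_depth()
    model = ConvClassifier(len(classes), input_size=size, base=base, depth=depth, seed=config.seed)
    opt = nn.Adam(model.layers(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    aug_cfg = DetectorConfig(
        input_size=max(8, size - size % 8),
        augmentation=config.augmentation,
        seed=config.seed,
    )
    dummy_boxes = [BBox(0, 0, 1, 1)] * len(labels)

    log: list[dict] = []
    best_metric, best_state, best_epoch, since_best = -np.inf, None, 0, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            bimgs, _ = _augmented_batch(images, dummy_boxes, idx, aug_cfg, rng)
            loss, grad = nn.softmax_cross_entropy(model.forward(bimgs), labels[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_pred = _predict_indices(model, images[va], config.batch_size)
        if stop_metric == "macro_f1":
            val_metric = float(
                skmetrics.f1_score(labels[va], val_pred, average="macro", zero_division=0)
            )
        else:
            val_metric = float(skmetrics.accuracy_score(labels[va], val_pred))
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), f"val_{stop_metric}": val_metric}
        )
        if val_metric > best_metric:
            best_metric, best_state, best_epoch, since_best = val_metric, _state_dict(model), epoch, 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    if best_state is not None:
        _load_state(model, best_state)
    return TrainedClassifier(
        model=model, config=config, task=task, classes=classes, training_log=log, best_epoch=best_epoch
    )


def _predict_indices(model: ConvClassifier, images: np.ndarray, batch: int) -> np.ndarray:
    return np.concatenate(
        [
            np.argmax(model.forward(images[s : s + batch]), axis=1)
            for s in range(0, len(images), batch)
        ]
    )


def predict_proba(clf: TrainedClassifier, images_raw: Sequence[np.ndarray]) -> np.ndarray:
    """Class probabilities (softmax) for a list of raw images."""
    size = clf.config.input_size
    images, _ = _prepare([(img, BBox(0, 0, 1, 1)) for img in images_raw], size)
    probs = []
    for s in range(0, len(images), clf.config.batch_size):
        z = clf.model.forward(images[s : s + clf.config.batch_size])
        zs = z - z.max(axis=1, keepdims=True)
        e = np.exp(zs)
        probs.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(probs)


@dataclass
class ClassifierReport:
    """Evaluation of one classifier on one labelled set.

    Per-class precision/recall/F1 come straight from the confusion matrix;
    macro averages are unweighted class means; AUC (binary task only) ranks
    the predicted probability of the difficult class.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "auc": self.auc,
        }


def report_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    classes: tuple[str, ...],
    difficult_scores: np.ndarray | None = None,
) -> ClassifierReport:
    """Build a report from integer labels/predictions (and binary scores)."""
    labels = np.arange(len(classes))
    conf = skmetrics.confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = skmetrics.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    per_class = {
        c: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for c, p, r, f in zip(classes, prec, rec, f1)
    }
    auc = None
    if difficult_scores is not None:
        if len(np.unique(y_true)) < 2:
            raise UndefinedAUCError("AUC undefined: evaluation set has a single class")
        auc = float(skmetrics.roc_auc_score(y_true, difficult_scores))
    return ClassifierReport(
        classes=classes,
        confusion=conf,
        per_class=per_class,
        accuracy=float(skmetrics.accuracy_score(y_true, y_pred)),
        macro_precision=float(np.mean(prec)),
        macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)),
        auc=auc,
    )


def evaluate_classifier(
    clf: TrainedClassifier,
    dataset: Sequence[tuple[np.ndarray, DifficultyLabel]],
    task: str | None = None,
) -> ClassifierReport:
    """Evaluate a trained classifier on a held-out labelled set."""
    task = task or clf.task
    classes = _classes_for(task)
    y_true = _label_indices([lab for _, lab in dataset], task)
    probs = predict_proba(clf, [img for img, _ in dataset])
    y_pred = np.argmax(probs, axis=1)
    scores = probs[:, 1] if task == "binary" else None
    return report_from_predictions(y_true, y_pred, classes, scores)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def kfold_harness(
    dataset: Sequence[tuple[np.ndarray, DifficultyLabel]],
    task: str = "binary",
    stop_metric: str = "macro_f1",
    config: ClassifierConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of the difficulty classifier.

    Returns ``{"folds": [ClassifierReport...], "fold_indices": [...],
    "mean": {...}, "sd": {...}}`` where mean/sd aggregate every scalar metric
    over the folds (population standard deviation).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(dataset) < k:
        raise ValueError(f"dataset size {len(dataset)} smaller than k={k}")
    config = config or ClassifierConfig()
    labels = _label_indices([lab for _, lab in dataset], task)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[ClassifierReport] = []
    fold_indices: list[list[int]] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        cfg = replace(config, seed=seed * 1000 + fold)
        train_ds = [dataset[i] for i in tr]
        test_ds = [dataset[i] for i in te]
        clf = train_difficulty_classifier(train_ds, task, stop_metric, cfg)
        reports.append(evaluate_classifier(clf, test_ds))
        fold_indices.append([int(i) for i in te])
    return {
        "folds": reports,
        "fold_indices": fold_indices,
        **aggregate_reports(reports),
    }


def aggregate_reports(reports: Sequence[ClassifierReport]) -> dict:
    """Mean and population sd of every scalar metric across fold reports."""

    def collect(report: ClassifierReport) -> dict[str, float]:
        flat = {
            "accuracy": report.accuracy,
            "macro_precision": report.macro_precision,
            "macro_recall": report.macro_recall,
            "macro_f1": report.macro_f1,
        }
        if report.auc is not None:
            flat["auc"] = report.auc
        for c, d in report.per_class.items():
            for m, v in d.items():
                flat[f"{c}_{m}"] = v
        return flat

    rows = [collect(r) for r in reports]
    keys = rows[0].keys()
    mean = {key: float(np.mean([row[key] for row in rows])) for key in keys}
    sd = {key: float(np.std([row[key] for row in rows])) for key in keys}
    return {"mean": mean, "sd": sd}
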