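"""Training wrapper, confusion-table metrics, and prediction helpers.

The heavy lifting lives in :class:`bsjnet.model.JunctionClassifier`; this
module keeps the procedural surface (train / evaluate / predict on labeled
datasets) and the evaluation arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_io import LabeledDataset
from .model import JunctionClassifier


@dataclass
class TrainConfig:
    """Training-loop knobs (defaults: Adam at the ablation-optimal 0.005)."""

    learning_rate: float = 0.005
    epochs: int = 30
    batch_size: int = 64
    optimizer: str = "adam"
    seed: int = 0
    early_stop_patience: int = 5
    class_weight: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class ConfusionTable:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionTable":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class EvalMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, defining the metric as 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(ct: ConfusionTable) -> EvalMetrics:
    """Closed-form metrics from the confusion table.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall (sensitivity)
    = TP/(TP+FN), F1 = harmonic mean of precision and recall, and
    MCC = (TP.TN - FP.FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any zero denominator yields 0 with a warning.
    """
    if ct.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = ct.tp, ct.fp, ct.tn, ct.fn
    accuracy = (tp + tn) / ct.total
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc")
    return EvalMetrics(accuracy, precision, recall, f1, mcc)


def train(
    embedder,
    train_set: LabeledDataset,
    val_set: LabeledDataset | None,
    tc: TrainConfig,
    **model_kwargs,
) -> JunctionClassifier:
    """Embed the datasets and fit a :class:`JunctionClassifier`.

    Deterministic given ``tc.seed`` (initialization and data order); with a
    validation set the returned model carries the parameters with the best
    validation loss (early stopping on that loss).
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    clf = JunctionClassifier(
        learning_rate=tc.learning_rate,
        epochs=tc.epochs,
        batch_size=tc.batch_size,
        optimizer=tc.optimizer,
        early_stop_patience=tc.early_stop_patience,
        class_weight=tc.class_weight,
        random_state=tc.seed,
        **model_kwargs,
    )
    X = embedder.transform(train_set.sequences)
    val = None
    if val_set is not None and len(val_set):
        val = (embedder.transform(val_set.sequences), val_set.labels)
    clf.fit(X, train_set.labels, validation_data=val)
    return clf


def evaluate(
    clf: JunctionClassifier, embedder, test_set: LabeledDataset
) -> tuple[ConfusionTable, EvalMetrics]:
    """Argmax predictions on the test split -> confusion table + metrics."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    y_pred = clf.predict(embedder.transform(test_set.sequences))
    ct = ConfusionTable.from_predictions(test_set.labels, y_pred)
    return ct, compute_metrics(ct)


def predict(clf: JunctionClassifier, sequences, embedder) -> list[tuple[int, np.ndarray]]:
    """Per-sequence (predicted label, probability vector), input order kept."""
    if not len(sequences):
        return []
    probs = clf.predict_proba(embedder.transform(sequences))
    return [(int(p.argmax()), p) for p in probs]
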