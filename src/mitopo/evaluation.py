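"""Split protocol, decoding metrics, and activation export.

The evaluation protocol shuffles the trial set with a fixed seed
(default 42) and holds out 25% for testing.  Metrics are the standard
decoding set: accuracy, Cohen's kappa against a fixed chance rate
(0.5 for the binary task), recall/precision/F1 for a designated
positive class, and the row-wise (actual x predicted) confusion matrix.

Subject-level accuracy is the unweighted mean of per-subject rates
R_i / S_i (each subject counts equally regardless of trial count); the
pooled-count alternative is provided separately under its own name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "split",
    "average_accuracy",
    "pooled_accuracy",
    "kappa",
    "recall_f1",
    "confusion_matrix",
    "evaluate_predictions",
    "export_activations",
]


@dataclass(frozen=True)
class SplitSpec:
    """75/25 shuffle split with a fixed seed; optional stratification."""

    train_fraction: float = 0.75
    shuffle_seed: int = 42
    stratified: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


def split(
    data: np.ndarray,
    labels: np.ndarray,
    spec: SplitSpec | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Deterministic shuffled partition into (train, test) pairs."""
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    strat = labels if spec.stratified else None
    x_tr, x_te, y_tr, y_te = train_test_split(
        data,
        labels,
        train_size=spec.train_fraction,
        random_state=spec.shuffle_seed,
        shuffle=True,
        stratify=strat,
    )
    if len(np.unique(y_tr)) < len(np.unique(labels)):
        raise ValueError("a class is empty after the split; use more trials")
    return (x_tr, y_tr), (x_te, y_te)


def average_accuracy(per_subject: Sequence[tuple[int, int]]) -> float:
    """Unweighted mean of per-subject accuracies, in percent.

    ``per_subject`` holds (correct R_i, total S_i) pairs; every subject
    contributes equally, which differs from pooling counts whenever
    subjects have unequal trial totals.
    """
    if not per_subject:
        raise ValueError("no subjects")
    rates = []
    for r, s in per_subject:
        if s <= 0:
            raise ValueError("subject with no evaluated trials")
        rates.append(r / s)
    return float(np.mean(rates) * 100.0)


def pooled_accuracy(per_subject: Sequence[tuple[int, int]]) -> float:
    """Accuracy from pooled counts across subjects, in percent."""
    if not per_subject:
        raise ValueError("no subjects")
    r = sum(r for r, _ in per_subject)
    s = sum(s for _, s in per_subject)
    return 100.0 * r / s


def kappa(po: float, pe: float = 0.5) -> float:
    """Chance-corrected agreement (Po - Pe) / (1 - Pe).

    For the balanced binary task the chance rate Pe is fixed at 0.5,
    which reduces kappa to 2 Po - 1.
    """
    if pe >= 1:
        raise ValueError("chance rate Pe must be < 1")
    return (po - pe) / (1.0 - pe)


def confusion_matrix(
    labels: np.ndarray,
    predictions: np.ndarray,
    classes: Sequence | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Counts with actual classes on rows and predicted on columns."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([labels, predictions]))
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=float)
    for t, p in zip(labels, predictions):
        counts[index[t], index[p]] += 1
    if normalize:
        row_sums = counts.sum(axis=1, keepdims=True)
        counts = np.divide(
            counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0
        )
    return counts


def recall_f1(
    confusion: np.ndarray, positive_class: int = 0
) -> tuple[float, float, float]:
    """(recall, precision, F1) for one positive class of a count matrix.

    Recall = TP / (TP + FN); F1 is the harmonic mean of precision and
    recall (0 when both vanish).  With no actual positive samples the
    recall is undefined and returned as NaN rather than silently 0.
    """
    confusion = np.asarray(confusion, dtype=float)
    tp = confusion[positive_class, positive_class]
    fn = confusion[positive_class].sum() - tp
    fp = confusion[:, positive_class].sum() - tp
    recall = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    precision = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    if math.isnan(recall) or math.isnan(precision) or precision + recall == 0:
        f1 = 0.0 if precision + recall == 0 else math.nan
        if math.isnan(recall) or math.isnan(precision):
            f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return recall, precision, f1


@dataclass
class MetricsReport:
    """Bundle of decoding metrics for one labeled prediction set."""

    accuracy: float
    kappa: float
    recall: float
    precision: float
    f1: float
    confusion: np.ndarray
    classes: tuple
    per_subject: list[tuple[int, int]] | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
        }


def evaluate_predictions(
    labels: np.ndarray,
    predictions: np.ndarray,
    classes: Sequence | None = None,
    positive_class_index: int = 0,
    chance_rate: float = 0.5,
) -> MetricsReport:
    """All metrics at once from raw label/prediction pairs."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if classes is None:
        classes = sorted(np.unique(np.concatenate([labels, predictions])))
    conf = confusion_matrix(labels, predictions, classes=classes)
    accuracy = float(np.trace(conf) / conf.sum())
    recall, precision, f1 = recall_f1(conf, positive_class_index)
    return MetricsReport(
        accuracy=accuracy,
        kappa=kappa(accuracy, chance_rate),
        recall=recall,
        precision=precision,
        f1=f1,
        confusion=conf,
        classes=tuple(classes),
    )


def export_activations(model, batch: np.ndarray, layer_tag: str) -> np.ndarray:
    """Flattened activations at a named stage, ``[n x d]``.

    Stages: raw (the network input), conv1 (first spatial conv), pool1
    and pool2 (block outputs after the log), fc (hidden dense layer),
    softmax (output probabilities) — the feature sets typically fed to
    external embedding tools for inspection.
    """
    return model.activations(batch, layer_tag)
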