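"""Multiclass evaluation: confusion matrices, per-class precision/recall/F1,
macro-F1, accuracy, the four-to-two class collapse, and multi-trial
mean +/- STD summaries.

Class labels are 1-based indices (1..K), matching the canonical phenotype
indexing (control = 1).  For a class c with true-positive, false-positive
and false-negative counts TP_c, FP_c, FN_c:

    precision_c = TP_c / (TP_c + FP_c)
    recall_c    = TP_c / (TP_c + FN_c)
    F1_c        = 2 * precision_c * recall_c / (precision_c + recall_c)

macro-F1 is the arithmetic mean of the F1_c, and accuracy the fraction of
exactly-correct predictions.  Zero-denominator cases are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phenotypes import PathogenicClass

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "precision_recall_f1",
    "macro_f1",
    "accuracy",
    "binarize",
    "summarize_trials",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.class_order)


def _check_labels(y, k: int, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=int).ravel()
    if y.size and (y.min() < 1 or y.max() > k):
        bad = y[(y < 1) | (y > k)][0]
        raise ValueError(f"{name} contains out-of-range class index {bad} (K={k})")
    return y


def confusion(y_true, y_pred, k: int, class_order: list[str] | None = None) -> ConfusionMatrix:
    """Tally a K x K confusion matrix from 1-based class index vectors."""
    y_true = _check_labels(y_true, k, "y_true")
    y_pred = _check_labels(y_pred, k, "y_pred")
    if y_true.size != y_pred.size:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    if class_order is None:
        if k == len(PathogenicClass):
            class_order = [c.label for c in PathogenicClass]
        else:
            class_order = [str(i) for i in range(1, k + 1)]
    return ConfusionMatrix(counts, list(class_order))


def precision_recall_f1(
    cm: ConfusionMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class precision, recall and F1 from a confusion matrix.

    Any zero denominator (class never predicted / never present / P+R = 0)
    yields 0 for the affected metric.
    """
    tp = np.diag(cm.counts).astype(float)
    fp = cm.counts.sum(axis=0) - tp
    fn = cm.counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return precision, recall, f1


def macro_f1(per_class_f1) -> float:
    """Arithmetic mean of the per-class F1 scores."""
    f1 = np.asarray(per_class_f1, dtype=float).ravel()
    if f1.size == 0:
        raise ValueError("macro_f1 of an empty class list is undefined")
    return float(f1.mean())


def accuracy(y_true, y_pred) -> float:
    """Fraction of samples whose prediction equals the true class."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size == 0:
        raise ValueError("accuracy of an empty sample is undefined")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch between y_true and y_pred")
    return float(np.mean(y_true == y_pred))


def binarize(y) -> np.ndarray:
    """Collapse the 4-class labels to control-vs-pathogenic.

    control (index 1) maps to the negative class 0; the three pathogenic
    mechanisms (indices 2..4) map to the positive class 1.
    """
    y = _check_labels(y, 4, "labels")
    return (y != PathogenicClass.control.index).astype(int)


@dataclass
class EvaluationReport:
    """All printed metrics for one model on one test set."""

    confusion: ConfusionMatrix
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    accuracy: float
    n: int

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, k: int, class_order: list[str] | None = None
    ) -> "EvaluationReport":
        cm = confusion(y_true, y_pred, k, class_order)
        p, r, f1 = precision_recall_f1(cm)
        return cls(
            confusion=cm,
            precision=p,
            recall=r,
            f1=f1,
            macro_f1=macro_f1(f1),
            accuracy=accuracy(y_true, y_pred),
            n=cm.n,
        )

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.confusion.class_order),
            "confusion": self.confusion.counts.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        cm = ConfusionMatrix(np.array(d["confusion"]), list(d["class_order"]))
        return cls(
            confusion=cm,
            precision=np.array(d["precision"]),
            recall=np.array(d["recall"]),
            f1=np.array(d["f1"]),
            macro_f1=float(d["macro_f1"]),
            accuracy=float(d["accuracy"]),
            n=int(d["n"]),
        )


def evaluate_predictions(y_true, y_pred, k: int = 4, class_order=None) -> EvaluationReport:
    """Convenience wrapper building a full :class:`EvaluationReport`."""
    return EvaluationReport.from_predictions(y_true, y_pred, k, class_order)


def summarize_trials(reports: list[EvaluationReport], with_std: bool = True) -> dict:
    """Mean and sample STD (n-1) of macro-F1 and accuracy across trials."""
    if not reports:
        raise ValueError("no reports to summarize")
    if with_std and len(reports) < 2:
        raise ValueError("sample STD requires at least two reports")
    f1s = np.array([r.macro_f1 for r in reports])
    accs = np.array([r.accuracy for r in reports])
    out = {
        "n_trials": len(reports),
        "macro_f1_mean": float(f1s.mean()),
        "accuracy_mean": float(accs.mean()),
    }
    if with_std:
        out["macro_f1_std"] = float(f1s.std(ddof=1))
        out["accuracy_std"] = float(accs.std(ddof=1))
    return out
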