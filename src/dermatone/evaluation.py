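"""Scoring predicted FST classes against ground truth.

Beyond the usual confusion matrix and exact-match metrics, FST prediction is
conventionally judged with an ordinal tolerance: a prediction within one
class of the ground truth is clinically acceptable, so the +/-1 tolerance
accuracy is reported alongside the exact metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LabeledPredictions",
    "EvaluationReport",
    "confusion_matrix",
    "classification_metrics",
    "tolerance_accuracy",
    "evaluate",
]

N_CLASSES = 6


@dataclass
class LabeledPredictions:
    """Per-image (predicted, true) FST pairs, classes in 1..6, unique image ids."""

    records: list[tuple[str, int, int]]  # (image_id, predicted_fst, true_fst)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("image_ids must be unique")
        for _, p, t in self.records:
            if not (1 <= p <= N_CLASSES and 1 <= t <= N_CLASSES):
                raise ValueError(f"FST classes must be in 1..{N_CLASSES}, got ({p}, {t})")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledPredictions":
        return cls(
            records=[
                (str(r.image_id), int(r.predicted_fst), int(r.true_fst))
                for r in df.itertuples(index=False)
            ]
        )

    @property
    def predicted(self) -> np.ndarray:
        return np.array([p for _, p, _ in self.records])

    @property
    def true(self) -> np.ndarray:
        return np.array([t for _, _, t in self.records])


@dataclass
class EvaluationReport:
    confusion: np.ndarray       # 6x6, rows = truth, columns = prediction
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    tolerance_accuracy: float
    tolerance: int
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": round(self.accuracy, 9),
            "precision_macro": round(self.precision_macro, 9),
            "recall_macro": round(self.recall_macro, 9),
            "f1_macro": round(self.f1_macro, 9),
            "tolerance": self.tolerance,
            "tolerance_accuracy": round(self.tolerance_accuracy, 9),
            "confusion": self.confusion.tolist(),
        }


def confusion_matrix(data: LabeledPredictions) -> np.ndarray:
    """6x6 count matrix: entry (t-1, p-1) counts true class t predicted as p."""
    mat = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(mat, (data.true - 1, data.predicted - 1), 1)
    return mat


def classification_metrics(
    confusion: np.ndarray, average: str = "macro"
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1) from a truth-by-prediction matrix.

    Macro averages run over classes present in the truth (non-zero row sum);
    a class never predicted contributes precision 0. ``average="micro"``
    gives the pooled metrics (all equal to accuracy for single-label data).
    """
    mat = np.asarray(confusion, dtype=float)
    total = mat.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(mat)
    accuracy = diag.sum() / total
    if average == "micro":
        return accuracy, accuracy, accuracy, accuracy
    if average != "macro":
        raise ValueError("average must be 'macro' or 'micro'")
    rowsum = mat.sum(axis=1)
    colsum = mat.sum(axis=0)
    present = rowsum > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, diag / np.where(colsum > 0, colsum, 1), 0.0)
        recall = np.where(rowsum > 0, diag / np.where(rowsum > 0, rowsum, 1), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / np.where(precision + recall > 0, precision + recall, 1),
            0.0,
        )
    return (
        float(accuracy),
        float(precision[present].mean()),
        float(recall[present].mean()),
        float(f1[present].mean()),
    )


def tolerance_accuracy(data: LabeledPredictions, tolerance: int = 1) -> float:
    """Fraction of predictions within ``tolerance`` ordinal classes of truth."""
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    return float(np.mean(np.abs(data.predicted - data.true) <= tolerance))


def evaluate(data: LabeledPredictions, tolerance: int = 1) -> EvaluationReport:
    """Full scoring pass: confusion matrix, exact metrics, tolerance accuracy."""
    mat = confusion_matrix(data)
    acc, prec, rec, f1 = classification_metrics(mat)
    tol_acc = tolerance_accuracy(data, tolerance)
    return EvaluationReport(
        confusion=mat,
        accuracy=acc,
        precision_macro=prec,
        recall_macro=rec,
        f1_macro=f1,
        tolerance_accuracy=tol_acc,
        tolerance=tolerance,
        n=len(data.records),
    )
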