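"""Imbalance-aware classification metrics.

All quantities are derived from the C x C confusion matrix (rows = true
class, columns = predicted class): per-class precision/recall/F1, their
macro (unweighted) and weighted (support-weighted) averages, accuracy, and
the multiclass Matthews correlation coefficient in Gorodkin's
generalisation.  Undefined precision or recall (an empty column or row)
is reported as 0, the usual classification-report convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class EvalReport:
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    mcc: float
    class_names: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
                "support": self.support.tolist(),
            },
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f1": self.macro_f1},
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall, "f1": self.weighted_f1},
            "mcc": self.mcc,
            "class_names": list(self.class_names) if self.class_names else None,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        """Aligned text table in the style of a classification report."""
        names = self.class_names or tuple(str(i) for i in range(len(self.support)))
        width = max(12, max(len(n) for n in names) + 2)
        lines = [f"{'':<{width}}{'precision':>10}{'recall':>10}{'f1':>10}{'support':>10}"]
        for i, name in enumerate(names):
            lines.append(
                f"{name:<{width}}{self.precision[i]:>10.4f}{self.recall[i]:>10.4f}"
                f"{self.f1[i]:>10.4f}{self.support[i]:>10d}"
            )
        n = int(self.support.sum())
        lines.append("")
        lines.append(f"{'accuracy':<{width}}{'':>20}{self.accuracy:>10.4f}{n:>10d}")
        lines.append(
            f"{'macro avg':<{width}}{self.macro_precision:>10.4f}"
            f"{self.macro_recall:>10.4f}{self.macro_f1:>10.4f}{n:>10d}"
        )
        lines.append(
            f"{'weighted avg':<{width}}{self.weighted_precision:>10.4f}"
            f"{self.weighted_recall:>10.4f}{self.weighted_f1:>10.4f}{n:>10d}"
        )
        lines.append(f"{'MCC':<{width}}{'':>30}{self.mcc:>10.4f}")
        return "\n".join(lines)


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """C x C count matrix with entry (i, j) = #{true = i and predicted = j}."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if len(y_true) and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    return np.bincount(
        y_true * num_classes + y_pred, minlength=num_classes * num_classes
    ).reshape(num_classes, num_classes)


def mcc(confusion: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin form).

    ``(N * trace - sum_k row_k col_k) / sqrt((N^2 - sum row^2)(N^2 - sum col^2))``
    with the convention that a zero denominator (e.g. every prediction in a
    single class) yields 0.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    n = cm.sum()
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    num = n * np.trace(cm) - row @ col
    den = np.sqrt((n * n - row @ row) * (n * n - col @ col))
    return float(num / den) if den > 0 else 0.0


def classification_report(
    confusion: np.ndarray, class_names: tuple[str, ...] | None = None
) -> EvalReport:
    """Full per-class and aggregate report from a confusion matrix."""
    cm = np.asarray(confusion, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = int(cm.sum())
    if n == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm).astype(np.float64)
    row = cm.sum(axis=1).astype(np.float64)   # support (true counts)
    col = cm.sum(axis=0).astype(np.float64)   # predicted counts
    if np.any((col == 0) | (row == 0)):
        warnings.warn(
            "precision/recall undefined for some class (empty row or column); reported as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    support = row.astype(np.int64)
    weights = row / n
    return EvalReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=float(diag.sum() / n),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float(weights @ precision),
        weighted_recall=float(weights @ recall),
        weighted_f1=float(weights @ f1),
        mcc=mcc(cm),
        class_names=class_names,
    )


def plot_confusion_heatmap(report: EvalReport, path: str | Path) -> None:
    """Render the confusion matrix as a heatmap image (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion
    names = report.class_names or tuple(str(i) for i in range(len(cm)))
    fig, ax = plt.subplots(figsize=(0.6 * len(cm) + 2, 0.6 * len(cm) + 2))
    im = ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(len(cm)), names, rotation=90)
    ax.set_yticks(range(len(cm)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
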