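"""Confusion matrix and classification metrics.

All scalar metrics are one-vs-rest: for class c, TP is the diagonal cell,
FN the rest of row c, FP the rest of column c and TN everything else.  From
these, per class (all in percent):

    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    precision   = TP / (TP + FP) * 100
    sensitivity = TP / (TP + FN) * 100          (= recall)
    specificity = TN / (TN + FP) * 100

Report scalars are macro averages over classes with at least one true sample;
micro accuracy (trace / total) is reported alongside.  Two AUC conventions
are provided: ``roc`` (default) is the macro one-vs-rest area under the ROC
curve computed from class probabilities; ``eq11_ratio`` is the legacy ratio
macro-sensitivity / macro-specificity * 100, retained for comparability with
reports that define AUC that way.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .image import CLASS_NAMES, N_CLASSES


@dataclass
class ConfusionMatrix:
    """Square count table: rows = true class, columns = predicted class."""

    table: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        n = len(self.class_names)
        if self.table.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} table")
        if (self.table < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.table, index=list(self.class_names),
                     columns=list(self.class_names)).to_csv(path)


@dataclass
class MetricsReport:
    """Macro one-vs-rest metrics in percent, plus per-class detail."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    auc: float
    micro_accuracy: float
    per_class_accuracy: dict[str, float]
    auc_mode: str = "roc"
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "auc": self.auc, "micro_accuracy": self.micro_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "auc_mode": self.auc_mode, "per_class": self.per_class,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        lines = [f"accuracy     {self.accuracy:6.2f}%  (micro {self.micro_accuracy:.2f}%)",
                 f"precision    {self.precision:6.2f}%",
                 f"sensitivity  {self.sensitivity:6.2f}%",
                 f"specificity  {self.specificity:6.2f}%",
                 f"auc [{self.auc_mode}]   {self.auc:6.2f}%",
                 "per-class accuracy (recall): " + ", ".join(
                     f"{c}={v:.1f}%" for c, v in self.per_class_accuracy.items())]
        return "\n".join(lines)


def confusion(y_true, y_pred, class_names: tuple[str, ...] = CLASS_NAMES
              ) -> ConfusionMatrix:
    """Count table over all classes (including empty ones)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = len(class_names)
    if y_true.size and (y_true.min() < 0 or y_true.max() >= n
                        or y_pred.min() < 0 or y_pred.max() >= n):
        raise ValueError(f"labels must be in 0..{n - 1}")
    table = _sk_confusion(y_true, y_pred, labels=np.arange(n))
    return ConfusionMatrix(table, class_names)


def metrics(cm: ConfusionMatrix, *, y_true=None, probabilities=None,
            auc_mode: str = "roc") -> MetricsReport:
    """Compute the metrics report from a confusion matrix.

    ``roc`` AUC additionally needs ``y_true`` and the (n, n_classes)
    probability matrix; without them the report falls back to ``eq11_ratio``.
    Classes with no true samples are excluded from the macro averages with a
    warning.
    """
    T = cm.table.astype(float)
    total = T.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    names = cm.class_names
    per_class: dict[str, dict[str, float]] = {}
    per_class_accuracy: dict[str, float] = {}
    macro: dict[str, list[float]] = {k: [] for k in
                                     ("accuracy", "precision", "sensitivity",
                                      "specificity")}
    for c, name in enumerate(names):
        tp = T[c, c]
        fn = T[c].sum() - tp
        fp = T[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {name!r} has no true samples; "
                          "excluded from macro averages")
            continue
        stats = {
            "accuracy": (tp + tn) / total * 100.0,
            "precision": tp / (tp + fp) * 100.0 if tp + fp > 0 else 0.0,
            "sensitivity": tp / (tp + fn) * 100.0,
            "specificity": tn / (tn + fp) * 100.0 if tn + fp > 0 else 0.0,
        }
        per_class[name] = stats
        per_class_accuracy[name] = stats["sensitivity"]
        for key, value in stats.items():
            macro[key].append(value)

    scalars = {k: float(np.mean(v)) for k, v in macro.items()}
    micro = float(np.trace(T) / total * 100.0)

    if auc_mode == "roc" and probabilities is not None and y_true is not None:
        y_true = np.asarray(y_true)
        present = np.unique(y_true)
        probs = np.asarray(probabilities)
        if present.size == 2:
            auc = float(roc_auc_score(y_true == present[1],
                                      probs[:, present[1]]) * 100.0)
        else:
            if present.size < len(names):
                probs = probs[:, present]
                probs = probs / probs.sum(axis=1, keepdims=True)
            auc = float(roc_auc_score(y_true, probs, multi_class="ovr",
                                      average="macro", labels=present) * 100.0)
        mode = "roc"
    else:
        auc = (scalars["sensitivity"] / scalars["specificity"] * 100.0
               if scalars["specificity"] > 0 else 0.0)
        mode = "eq11_ratio"

    return MetricsReport(accuracy=scalars["accuracy"],
                         precision=scalars["precision"],
                         sensitivity=scalars["sensitivity"],
                         specificity=scalars["specificity"],
                         auc=auc, micro_accuracy=micro,
                         per_class_accuracy=per_class_accuracy,
                         auc_mode=mode, per_class=per_class)


def evaluate(y_true, y_pred, probabilities=None, auc_mode: str = "roc",
             class_names: tuple[str, ...] = CLASS_NAMES) -> MetricsReport:
    """Convenience wrapper: confusion + metrics in one call."""
    cm = confusion(y_true, y_pred, class_names)
    return metrics(cm, y_true=y_true, probabilities=probabilities,
                   auc_mode=auc_mode)
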