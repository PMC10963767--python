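"""Classification metrics: accuracy, weighted P/R/F1, confusion, ROC.

Averaging is support-weighted (macro available via flag): the weighted
recall then equals overall accuracy algebraically, a useful internal
consistency check. Classes absent from the evaluated set are flagged
undefined per class and excluded from the weighted averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_curve


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float | None]]
    confusion: np.ndarray
    roc: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    classes: tuple[str, ...] = ()
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "roc": self.roc,
            "classes": list(self.classes),
            "n": self.n,
        }


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probabilities: np.ndarray | None = None,
    classes: tuple[str, ...] = (),
    average: str = "weighted",
) -> MetricsReport:
    """Build a full report from true/predicted label indices.

    Percentages are on the 0–100 scale. ``probabilities`` (n, K) enables
    one-vs-rest ROC curves per class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("cannot compute metrics on an empty evaluation set")
    K = len(classes) if classes else int(max(y_true.max(), y_pred.max())) + 1
    names = tuple(classes) if classes else tuple(str(i) for i in range(K))
    present = sorted(set(y_true.tolist()))

    acc = float(np.mean(y_true == y_pred)) * 100.0
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average=average, zero_division=0
    )
    pc_p, pc_r, pc_f, pc_s = precision_recall_fscore_support(
        y_true, y_pred, labels=list(range(K)), average=None, zero_division=0
    )
    per_class: dict[str, dict[str, float | None]] = {}
    for i, name in enumerate(names):
        if i in present:
            per_class[name] = {
                "precision": float(pc_p[i]) * 100.0,
                "recall": float(pc_r[i]) * 100.0,
                "f1": float(pc_f[i]) * 100.0,
                "support": int(pc_s[i]),
            }
        else:
            per_class[name] = {"precision": None, "recall": None, "f1": None, "support": 0}

    cm = confusion_matrix(y_true, y_pred, labels=list(range(K)))

    roc: dict[str, dict[str, list[float]]] = {}
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        for i in present:
            fpr, tpr, thr = roc_curve((y_true == i).astype(int), probabilities[:, i])
            roc[names[i]] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "thresholds": thr.tolist()}

    return MetricsReport(
        accuracy=acc,
        precision=float(p) * 100.0,
        recall=float(r) * 100.0,
        f1=float(f) * 100.0,
        per_class=per_class,
        confusion=cm,
        roc=roc,
        classes=names,
        n=int(y_true.size),
    )
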