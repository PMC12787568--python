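"""One-vs-all classification metrics and inter-subject pooling.

Per-frame gold and predicted activity labels are scored with the standard
one-vs-all decomposition: per class precision, recall and F1, macro and
support-weighted averages, overall accuracy, and a 4x4 confusion matrix in
raw counts and row-normalized percentages.  Inter-subject performance pools
the raw label arrays of all athletes into one pair before computing the same
metrics (a micro average, not an average of per-athlete metrics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

from .signal_model import Activity

__all__ = ["ClassificationReport", "report", "pool"]

_LABELS = [int(a) for a in Activity]
_NAMES = [a.label for a in Activity]


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class and aggregate one-vs-all metrics on frame labels.

    Metrics are fractions in [0, 1]; ``undefined`` flags classes whose
    precision or F1 had a zero denominator and was reported as 0.  The
    confusion matrix rows are gold classes, columns predictions.
    """

    per_class: pd.DataFrame
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    accuracy: float
    confusion: pd.DataFrame
    confusion_pct: pd.DataFrame
    undefined: tuple[str, ...]

    @property
    def support(self) -> pd.Series:
        return self.per_class["support"]

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="index"),
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "accuracy": self.accuracy,
            "undefined": list(self.undefined),
        }

    def summary(self) -> str:
        lines = [self.per_class.to_string(float_format=lambda v: f"{v:.4f}")]
        lines.append(
            f"macro avg     precision {self.macro_avg['precision']:.4f}  "
            f"recall {self.macro_avg['recall']:.4f}  f1 {self.macro_avg['f1']:.4f}"
        )
        lines.append(
            f"weighted avg  precision {self.weighted_avg['precision']:.4f}  "
            f"recall {self.weighted_avg['recall']:.4f}  f1 {self.weighted_avg['f1']:.4f}"
        )
        lines.append(f"accuracy      {self.accuracy:.4f}")
        return "\n".join(lines)


def report(
    gold: np.ndarray, pred: np.ndarray, mask: np.ndarray | None = None
) -> ClassificationReport:
    """Score predicted frame labels against the gold standard.

    ``mask`` selects the frames that count (edge-duplicate frames in
    cross-validation test sets are excluded through it).  Classes absent from
    both arrays get support 0 and their undefined metrics are reported as 0
    with a flag.
    """
    gold = np.asarray(gold).ravel()
    pred = np.asarray(pred).ravel()
    if gold.shape != pred.shape:
        raise ValueError(
            f"gold and predicted arrays differ in length: {gold.size} vs {pred.size}"
        )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        if mask.shape != gold.shape:
            raise ValueError("mask length must match the label arrays")
        gold, pred = gold[mask], pred[mask]
    if gold.size == 0:
        raise ValueError("no scored frames (empty arrays or all-False mask)")

    precision, recall, f1, support = precision_recall_fscore_support(
        gold, pred, labels=_LABELS, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": support},
        index=pd.Index(_NAMES, name="class"),
    )
    undefined = []
    for i, name in enumerate(_NAMES):
        predicted_i = np.count_nonzero(pred == _LABELS[i])
        if predicted_i == 0 or support[i] == 0:
            undefined.append(name)
    present = support > 0
    macro = {
        "precision": float(precision[present].mean()),
        "recall": float(recall[present].mean()),
        "f1": float(f1[present].mean()),
    }
    weights = support / support.sum()
    weighted = {
        "precision": float((precision * weights).sum()),
        "recall": float((recall * weights).sum()),
        "f1": float((f1 * weights).sum()),
    }
    acc = float(accuracy_score(gold, pred))
    conf = confusion_matrix(gold, pred, labels=_LABELS)
    conf_df = pd.DataFrame(conf, index=pd.Index(_NAMES, name="gold"), columns=_NAMES)
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * conf / row_sums, 0.0)
    pct_df = pd.DataFrame(pct, index=conf_df.index.copy(), columns=_NAMES)
    return ClassificationReport(
        per_class=per_class,
        macro_avg=macro,
        weighted_avg=weighted,
        accuracy=acc,
        confusion=conf_df,
        confusion_pct=pct_df,
        undefined=tuple(undefined),
    )


def pool(pairs: list[tuple[np.ndarray, np.ndarray]]) -> ClassificationReport:
    """Inter-subject metrics from concatenated raw label arrays.

    ``pairs`` holds one (gold, pred) pair per athlete, already restricted to
    scored frames.  Arrays are concatenated and scored as a single subject;
    supports add across athletes.
    """
    if not pairs:
        raise ValueError("pool needs at least one (gold, pred) pair")
    gold = np.concatenate([np.asarray(g).ravel() for g, _ in pairs])
    pred = np.concatenate([np.asarray(p).ravel() for _, p in pairs])
    return report(gold, pred)
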