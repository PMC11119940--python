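"""Imbalance-aware evaluation metrics from an accumulated confusion matrix.

With per-class true/false positives and negatives (TP_c, FP_c, FN_c):

    Rec_c = TP_c / (TP_c + FN_c)        MRec = mean_c Rec_c
    Pre_c = TP_c / (TP_c + FP_c)        MPre = mean_c Pre_c
    MF1   = 2·MPre·MRec / (MPre + MRec)
    Acc   = Σ_c TP_c / N
    GM    = ( Π_c S_c )^(1/C)           S_c = sensitivity = Rec_c

Macro averages weight every class equally, which is what matters under a
long-tailed class distribution; GM is the geometric mean of per-class
sensitivities, with zero sensitivities floored at 0.001 so a single missed
class penalises GM heavily without annihilating it.

Conventions for degenerate classes: a class that is never predicted
(TP + FP = 0) contributes precision 0 to MPre; a class with no true samples
contributes recall 0.  All metrics are computed from one accumulated
confusion matrix, never by averaging per-batch values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "compute_metrics"]

SENSITIVITY_FLOOR = 0.001


def confusion(pred, truth, num_classes: int) -> np.ndarray:
    """Confusion matrix [C, C]; rows = true class, columns = predicted."""
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D vectors")
    if pred.size and (min(pred.min(), truth.min()) < 0
                      or max(pred.max(), truth.max()) >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


ConfusionMatrix = np.ndarray  # alias for signatures


@dataclass
class MetricsReport:
    acc: float
    mpre: float
    mrec: float
    mf1: float
    gm: float
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "mpre": self.mpre, "mrec": self.mrec,
            "mf1": self.mf1, "gm": self.gm,
            "per_class": {k: list(map(float, v)) for k, v in self.per_class.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path=None) -> str:
        lines = ["metric\tvalue"]
        for k in ("acc", "mpre", "mrec", "mf1", "gm"):
            lines.append(f"{k}\t{getattr(self, k):.6f}")
        lines.append("class\tprecision\trecall\tsensitivity")
        pre = self.per_class["precision"]
        rec = self.per_class["recall"]
        sen = self.per_class["sensitivity"]
        for c, (p, r, s) in enumerate(zip(pre, rec, sen)):
            lines.append(f"{c}\t{p:.6f}\t{r:.6f}\t{s:.6f}")
        text = "\n".join(lines)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compute_metrics(cm: np.ndarray) -> MetricsReport:
    """Compute the full metric suite from a confusion matrix."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total < 1:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm).astype(np.float64)
    support = cm.sum(axis=1).astype(np.float64)   # TP + FN per class
    predicted = cm.sum(axis=0).astype(np.float64)  # TP + FP per class

    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, tp / support, 0.0)
        precision = np.where(predicted > 0, tp / predicted, 0.0)

    mrec = float(recall.mean())
    mpre = float(precision.mean())
    mf1 = 0.0 if mpre + mrec == 0 else 2.0 * mpre * mrec / (mpre + mrec)
    acc = float(tp.sum() / total)

    sensitivity = recall.copy()
    floored = np.where(sensitivity == 0.0, SENSITIVITY_FLOOR, sensitivity)
    gm = float(np.exp(np.mean(np.log(floored))))

    return MetricsReport(
        acc=acc, mpre=mpre, mrec=mrec, mf1=float(mf1), gm=gm,
        per_class={"precision": precision, "recall": recall,
                   "sensitivity": sensitivity},
    )
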