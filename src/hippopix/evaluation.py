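"""Confusion-matrix metrics, ROC/AUC, and the 7-vs-14-feature comparison.

The positive class is C1 (hippocampal pixel). Rates follow the standard
definitions: recall (TPR) = TP/(TP+FN), precision = TP/(TP+FP),
FPR = FP/(FP+TN); F1 is the harmonic mean of precision and recall. The ROC
curve sweeps all distinct score thresholds in descending order (equal
scores collapse into one step) and AUC is the trapezoidal area under it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import FAMILIES, ClassifierSpec, predict, train
from .dataset import DataSplit

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate",
    "compare_feature_sets",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalReport:
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    roc: np.ndarray | None = None  # (n, 2) columns FPR, TPR
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """2x2 counts with C1 (label 1) as the positive class."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1); zero-denominator cases give 0."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.tp + counts.tn) / counts.total
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2.0 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical ROC (including the (0,0) and (1,1) endpoints) and its AUC.

    Thresholds sweep the distinct scores in descending order; tied scores
    form a single step, which makes the curve invariant under any strictly
    monotone transform of the scores.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    # keep only the last index of each tied-score run
    last = np.nonzero(np.diff(ss, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate(labels: np.ndarray, scores: np.ndarray, predictions: np.ndarray) -> EvalReport:
    """Full report: confusion counts, the four threshold metrics, ROC and AUC."""
    counts = confusion(labels, predictions)
    acc, prec, rec, f1 = metrics(counts)
    roc, auc = roc_auc(labels, scores)
    degenerate = (counts.tp + counts.fp == 0) or (counts.tp + counts.fn == 0)
    return EvalReport(
        counts=counts,
        accuracy=acc,
        precision=prec,
        recall=rec,
        f1=f1,
        auc=auc,
        roc=roc,
        degenerate=degenerate,
    )


def evaluate_model(model, part) -> EvalReport:
    """Evaluate a trained model on a labelled set (typically D_TS)."""
    scores, preds = predict(model, part)
    return evaluate(part.y(), scores, preds)


def compare_feature_sets(
    data: DataSplit,
    families: tuple[str, ...] = FAMILIES,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-family test accuracy with 7 vs 14 features, plus the mean row.

    Reproduces the benchmark-table layout: one row per family with both
    accuracies and their difference, and a final cross-family average.
    """
    rows = []
    for fam in families:
        accs = {}
        for nf in (7, 14):
            model = train(ClassifierSpec(family=fam, seed=seed, n_features=nf), data)
            rep = evaluate_model(model, data.test)
            accs[nf] = rep.accuracy
        rows.append(
            {
                "model": fam,
                "accuracy_7": accs[7],
                "accuracy_14": accs[14],
                "difference": accs[14] - accs[7],
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {
        "model": "mean",
        "accuracy_7": df["accuracy_7"].mean(),
        "accuracy_14": df["accuracy_14"].mean(),
        "difference": df["difference"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
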