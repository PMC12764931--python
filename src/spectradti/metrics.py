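"""Classification metrics: AUC-ROC (rank statistic), AUPR (step integration),
thresholded confusion metrics, and fold aggregation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricsReport", "compute_metrics", "auc_roc", "aupr", "aggregate_folds"]


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney rank statistic with average ranks for ties."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision by step integration of the precision-recall curve."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    n_pos = tp[-1]
    if n_pos == 0:
        raise ValueError("AUPR undefined without positives")
    # evaluate only at distinct score thresholds so ties form one step
    s = scores[order]
    last_of_group = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last_of_group], fp[last_of_group]
    precision = tp / np.maximum(tp + fp, 1)
    recall = tp / n_pos
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(precision * d_recall))


@dataclass
class MetricsReport:
    auc_roc: float
    aupr: float
    accuracy: float
    precision: float
    recall: float
    fpr: float
    f1: float
    threshold: float = 0.5
    n: int = 0
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "auc_roc": self.auc_roc, "aupr": self.aupr, "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall, "fpr": self.fpr,
            "f1": self.f1, "n": self.n,
        }
        d.update(self.extras)
        return d


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.size == 0:
        raise ValueError("empty inputs")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return MetricsReport(
        auc_roc=auc_roc(scores, labels),
        aupr=aupr(scores, labels),
        accuracy=(tp + tn) / scores.size,
        precision=precision,
        recall=recall,
        fpr=fpr,
        f1=f1,
        threshold=threshold,
        n=int(scores.size),
    )


def aggregate_folds(reports: list) -> dict:
    """Unweighted mean and standard deviation per metric across folds/runs."""
    keys = ["auc_roc", "aupr", "accuracy", "precision", "recall", "fpr", "f1"]
    out = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=np.float64)
        out[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return out
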