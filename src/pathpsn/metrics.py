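"""Evaluation metrics: MCC-centred classification report and the
cluster-vs-class Jaccard of a network's topology."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .psn import SimilarityNetwork

logger = logging.getLogger(__name__)


def matthews_corrcoef(y_true, y_pred) -> float:
    """MCC from the 2x2 confusion table; a zero denominator yields 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label collections must have equal length")
    classes = np.unique(y_true)
    if len(classes) > 2:
        raise ValueError(f"binary MCC expects two classes, got {classes}")
    pos = classes[0]
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


@dataclass
class MetricReport:
    """Confusion counts plus the derived binary-classification metrics."""

    mcc: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str

    def to_dict(self) -> dict:
        return {"mcc": self.mcc, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "positive_class": self.positive_class}


def classification_metrics(y_true, y_pred,
                           positive_class: str | None = None) -> MetricReport:
    """MCC, accuracy, sensitivity and specificity for two-class labels.

    Predicted labels must come from the set of true labels; by default the
    lexicographically first class is treated as positive.
    """
    y_true = pd.Series(list(y_true))
    y_pred = pd.Series(list(y_pred))
    if len(y_true) != len(y_pred):
        raise ValueError("label collections must have equal length")
    classes = sorted(y_true.unique())
    unseen = set(y_pred.unique()) - set(classes)
    if unseen:
        raise ValueError(f"predictions contain unseen labels: {sorted(unseen)}")
    if positive_class is None:
        positive_class = classes[0]
    tp = int(((y_true == positive_class) & (y_pred == positive_class)).sum())
    tn = int(((y_true != positive_class) & (y_pred != positive_class)).sum())
    fp = int(((y_true != positive_class) & (y_pred == positive_class)).sum())
    fn = int(((y_true == positive_class) & (y_pred != positive_class)).sum())
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else float((tp * tn - fp * fn) / denom)
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return MetricReport(mcc=mcc, accuracy=accuracy, sensitivity=sensitivity,
                        specificity=specificity, tp=tp, tn=tn, fp=fp, fn=fn,
                        positive_class=positive_class)


def cluster_class_jaccard(network: SimilarityNetwork, seed: int = 0) -> float:
    """Overlap between a 2-means clustering of the weight columns and the
    true classes, maximized over the two cluster/class pairings."""
    labels = np.array([network.labels[p] for p in network.patient_ids])
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected two classes, found {classes}")
    km = KMeans(n_clusters=2, random_state=seed, n_init=10)
    assign = km.fit_predict(network.weights)
    best = 0.0
    for pairing in ((0, 1), (1, 0)):
        jac = []
        for cls, clu in zip(classes, pairing):
            in_class = set(np.flatnonzero(labels == cls))
            in_cluster = set(np.flatnonzero(assign == clu))
            union = in_class | in_cluster
            jac.append(len(in_class & in_cluster) / len(union) if union else 1.0)
        best = max(best, float(np.mean(jac)))
    return best
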