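"""Classification metrics for the sex-prediction task (girls = 1, boys = 0)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "auc_score", "compute_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    """Balanced accuracy, class-conditional rates and AUC.

    The positive class is girls (label 1).  Scores are binarized at 0.5
    with ties assigned to class 0 (boy).  Balanced accuracy is the mean of
    TPR and TNR; AUC is the fraction of concordant (girl, boy) score pairs
    with ties counted 1/2.
    """

    balanced_accuracy: float
    tpr: float
    tnr: float
    fpr: float
    auc: float
    n_pos: int
    n_neg: int
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str = "girl"


def _placements(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Per-positive placement values: P(score > random negative) with ties 1/2."""
    cmp = (pos[:, None] > neg[None, :]).astype(np.float64)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by pairwise placement (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: need both classes")
    return float(_placements(pos, neg).mean())


def compute_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Binarize scores and report balanced accuracy, TPR/TNR/FPR and AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics undefined: need at least one subject of each class")
    pred = (scores > threshold).astype(int)  # ties at the threshold -> boy (0)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tpr = tp / n_pos
    tnr = tn / n_neg
    return MetricsReport(
        balanced_accuracy=(tpr + tnr) / 2.0,
        tpr=tpr,
        tnr=tnr,
        fpr=1.0 - tnr,
        auc=auc_score(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
    )
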