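"""Evaluation statistics and D-score ranking of candidate interactions.

The D-score of a sample is the logit of its positive-class probability,
ln(p / (1 - p)) — the signed distance from the softmax decision boundary.
Ranking unlabeled drug-gene pairs by D-score puts the most confident
candidate interactions first; a score of zero corresponds exactly to the
0.5 decision threshold used by the hard-call metrics.

PoPC (percentage of positive cases) is the fraction of unlabeled pairs
called positive: at fixed accuracy a lower PoPC marks a more conservative,
higher-precision predictor. The predictive error compares a second model's
classification matrix against the reference network's, at each sample's
true-class column: negative values mean the comparator assigns less
probability to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RankedPrediction",
    "MetricReport",
    "d_score",
    "predictive_error",
    "popc",
    "classification_metrics",
    "rank_by_d_score",
]

EPS = 1e-7


@dataclass(frozen=True)
class RankedPrediction:
    drug_id: str
    gene_id: str
    p_positive: float
    d_score: float


@dataclass(frozen=True)
class MetricReport:
    """Hard-call classification metrics with their underlying counts."""

    validation_accuracy: float
    f_score: float
    tp: int
    fp: int
    tn: int
    fn: int
    popc: Optional[float] = None
    n_unlabeled: int = 0
    n_predicted_positive: int = 0
    zero_denominator: bool = False


def d_score(p_positive: float | np.ndarray, eps: float = EPS) -> float | np.ndarray:
    """Logit of the positive-class probability, eps-clipped to stay finite."""
    p = np.asarray(p_positive, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p_positive must be finite")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p_positive must lie in [0, 1]")
    pc = np.clip(p, eps, 1.0 - eps)
    out = np.log(pc / (1.0 - pc))
    return float(out) if out.ndim == 0 else out


def predictive_error(
    cm_other: np.ndarray, cm_dnn: np.ndarray, labels: Sequence[int]
) -> np.ndarray:
    """Per-sample PE: comparator minus reference probability at the true class."""
    cm_other = np.asarray(cm_other, dtype=float)
    cm_dnn = np.asarray(cm_dnn, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if cm_other.shape != cm_dnn.shape or cm_other.shape[0] != labels.shape[0]:
        raise ValueError(
            f"misaligned inputs: other {cm_other.shape}, dnn {cm_dnn.shape}, "
            f"labels {labels.shape}"
        )
    idx = np.arange(labels.size)
    return cm_other[idx, labels] - cm_dnn[idx, labels]


def popc(cm_unlabeled: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of unlabeled samples with positive probability > threshold."""
    cm = np.asarray(cm_unlabeled, dtype=float)
    if cm.size == 0:
        raise ValueError("popc of an empty classification matrix is undefined")
    return float((cm[:, 1] > threshold).mean())


def classification_metrics(
    cm: np.ndarray,
    labels: Sequence[int],
    threshold: float = 0.5,
    cm_unlabeled: Optional[np.ndarray] = None,
) -> MetricReport:
    """Accuracy and positive-class F-score at a hard decision threshold.

    Zero-denominator precision or recall is reported as 0 with the
    ``zero_denominator`` flag set. If ``cm_unlabeled`` is supplied, PoPC on
    it is included in the report.
    """
    cm = np.asarray(cm, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if cm.shape[0] != labels.shape[0]:
        raise ValueError("labels misaligned with classification matrix")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes must be represented in labels")
    pred = (cm[:, 1] > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / labels.size
    flag = False
    if tp + fp == 0 or tp + fn == 0:
        precision = recall = 0.0
        flag = True
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    flag = flag or (precision + recall == 0)

    popc_val, n_unl, n_pp = None, 0, 0
    if cm_unlabeled is not None:
        popc_val = popc(cm_unlabeled, threshold)
        n_unl = int(np.asarray(cm_unlabeled).shape[0])
        n_pp = int((np.asarray(cm_unlabeled)[:, 1] > threshold).sum())
    return MetricReport(
        validation_accuracy=float(acc),
        f_score=float(f),
        tp=tp, fp=fp, tn=tn, fn=fn,
        popc=popc_val,
        n_unlabeled=n_unl,
        n_predicted_positive=n_pp,
        zero_denominator=flag,
    )


def rank_by_d_score(
    cm_unlabeled: np.ndarray, pair_ids: Sequence[Tuple[str, str]]
) -> List[RankedPrediction]:
    """Rank unlabeled pairs by descending D-score.

    Ties are broken by (drug_id, gene_id) lexicographic order so the ranking
    is identical across runs and platforms.
    """
    cm = np.asarray(cm_unlabeled, dtype=float)
    if cm.shape[0] != len(pair_ids):
        raise ValueError("pair ids misaligned with classification matrix")
    preds = [
        RankedPrediction(d, g, float(p), float(d_score(p)))
        for (d, g), p in zip(pair_ids, cm[:, 1])
    ]
    return sorted(preds, key=lambda r: (-r.d_score, r.drug_id, r.gene_id))
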