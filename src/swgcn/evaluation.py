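"""Ranking metrics over the held-out evaluation pairs.

AUC is the probability that a random positive outranks a random negative
(ties counted 1/2, i.e. the Mann-Whitney normalisation, which equals the
trapezoidal ROC area).  AUPR is average precision — the step-wise
precision-recall area, not the trapezoidal interpolation.  Both are
computed by scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .weighting import SplitSpec, _pair_set

__all__ = ["EvalReport", "auc", "aupr", "evaluate_split"]


@dataclass(frozen=True)
class EvalReport:
    auc: float
    aupr: float
    n_pos: int
    n_neg: int
    mode: str = ""


def auc(scores, labels) -> float:
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


def evaluate_split(u: np.ndarray, splits: SplitSpec, mode: str = "") -> EvalReport:
    """Score the held-out independent pairs of phase 2.

    Metrics use only ``ind2_pos`` (label 1) and ``ind2_neg`` (label 0);
    the balanced protocol keeps the two the same size.  Overlap between
    the evaluation pairs and any training positives is a hard error.
    """
    u = np.asarray(u)
    if u.shape != splits.shape:
        raise ValueError(f"score matrix shape {u.shape} != {splits.shape}")
    eval_pairs = _pair_set(splits.ind2_pos) | _pair_set(splits.ind2_neg)
    train_pos = _pair_set(splits.ben2_pos) | _pair_set(splits.ben1_pos)
    if eval_pairs & train_pos:
        raise ValueError("evaluation pairs overlap a training positive set")
    pos, neg = splits.ind2_pos, splits.ind2_neg
    scores = np.concatenate([u[pos[:, 0], pos[:, 1]], u[neg[:, 0], neg[:, 1]]])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return EvalReport(
        auc=auc(scores, labels),
        aupr=aupr(scores, labels),
        n_pos=len(pos),
        n_neg=len(neg),
        mode=mode,
    )
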