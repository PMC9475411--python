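"""Evaluation metrics and train/test splitting.

The metric suite is the standard binary-classification set: precision,
recall, F1 (harmonic mean of the two), accuracy, ROC AUC and PR AUC (the
latter computed as average precision, i.e. step-wise interpolation of the
precision-recall curve).  Ratios with a zero denominator are reported as 0
and flagged in ``undefined`` rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricsReport", "compute_metrics", "split_train_test"]


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    roc_auc: float
    pr_auc: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def _to_binary(y) -> np.ndarray:
    """Map labels in {+1,-1} or {1,0} onto {1,0}."""
    y = np.asarray(y)
    return (y > 0).astype(np.int64)


def compute_metrics(
    y_true: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    predictions: Sequence[int] | None = None,
) -> MetricsReport:
    """Threshold the scores, build the confusion counts, and compute the six
    metrics.  ROC/PR AUC come from the score ranking; when only one class is
    present they are undefined and reported as 0 with a flag.

    ``predictions`` overrides the thresholding for the confusion counts —
    used for classifiers (like the product-rule baseline) whose labeling is
    not a single cut on the score.
    """
    y = _to_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have the same length")
    if y.size == 0:
        raise ValueError("need at least one item")
    if predictions is not None:
        pred = _to_binary(predictions)
        if pred.shape != y.shape:
            raise ValueError("predictions must match y_true length")
    else:
        pred = (s >= threshold).astype(np.int64)

    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = (tp + tn) / y.size

    if np.unique(y).size < 2:
        undefined.extend(["roc_auc", "pr_auc"])
        roc = pr = 0.0
    else:
        roc = float(roc_auc_score(y, s))
        pr = float(average_precision_score(y, s))

    return MetricsReport(
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        accuracy=float(accuracy),
        roc_auc=roc,
        pr_auc=pr,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        undefined=tuple(undefined),
    )


def split_train_test(items: Sequence, ratio: float = 0.9, seed: int = 0):
    """Deterministic shuffled split; the training side gets ceil(n * ratio)
    items and the test side the remainder."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    items = list(items)
    if not items:
        raise ValueError("items must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = math.ceil(len(items) * ratio)
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test
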