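"""Multilabel label decision and evaluation metrics.

Decision: the threshold strategy assigns every label whose classifier score
reaches the threshold T; the guarantee strategy additionally assigns the
single highest-scoring label when no score reaches T, so predictions are
never empty.  T is tuned by grid search (default -2..2, step 0.1)
maximising subset accuracy.

Metrics (L = 6 classes, q samples, labels coded +/-1):

* subset accuracy — fraction of samples whose predicted label set equals
  the true set exactly;
* accuracy — mean per-sample Jaccard-style score
  ``point = |true ∩ pred| / |true ∪ pred|``;
* recall — per class l, the mean ``point`` over samples whose TRUE set
  contains l, averaged uniformly over classes;
* precision — per class l, the mean ``point`` over samples whose PREDICTED
  set contains l, averaged uniformly over classes;
* average label accuracy — per class l the fraction of samples with
  ``pred_l == true_l``, averaged over classes.

Classes with an empty denominator (never true / never predicted) are
skipped in the macro averages with a logged note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import N_CLASSES

log = logging.getLogger(__name__)


def decide(scores: np.ndarray, T: float, guarantee: bool = True) -> np.ndarray:
    """Score vector(s) -> +/-1 label vector(s) by threshold (+ guarantee).

    A label is assigned iff its score is >= T.  With ``guarantee``, if no
    score reaches T the single argmax label is assigned (ties break to the
    lowest index).  Accepts one score vector or an (n, L) matrix.
    """
    o = np.asarray(scores, float)
    if not np.all(np.isfinite(o)):
        raise ValueError("scores must be finite")
    single = o.ndim == 1
    o = np.atleast_2d(o)
    y = np.where(o >= T, 1.0, -1.0)
    if guarantee:
        none = ~(y > 0).any(axis=1)
        if none.any():
            top = o[none].argmax(axis=1)  # argmax ties -> lowest index
            y[np.flatnonzero(none), top] = 1.0
    return y[0] if single else y


def _point(truth_row: np.ndarray, pred_row: np.ndarray) -> float:
    """|true ∩ pred| / |true ∪ pred| on +/-1 rows."""
    t = truth_row > 0
    p = pred_row > 0
    union = (t | p).sum()
    return float((t & p).sum() / union) if union else 1.0


@dataclass
class MetricsReport:
    subset_accuracy: float
    accuracy: float
    recall: float
    precision: float
    average_label_accuracy: float
    per_label_accuracy: np.ndarray
    per_label_recall: np.ndarray
    per_label_precision: np.ndarray

    def as_dict(self) -> dict:
        return {
            "subset_accuracy": self.subset_accuracy,
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "average_label_accuracy": self.average_label_accuracy,
            "per_label_accuracy": self.per_label_accuracy.tolist(),
            "per_label_recall": self.per_label_recall.tolist(),
            "per_label_precision": self.per_label_precision.tolist(),
        }


def compute_metrics(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Five multilabel metrics over (q, 6) +/-1 prediction/truth matrices."""
    pred = np.atleast_2d(np.asarray(pred, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if pred.shape[1] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} classes")
    q = pred.shape[0]
    if q == 0:
        raise ValueError("empty prediction set")

    points = np.array([_point(t, p) for t, p in zip(truth, pred)])
    exact = np.array([np.array_equal(t > 0, p > 0) for t, p in zip(truth, pred)])

    subset_accuracy = float(exact.mean())
    accuracy = float(points.mean())

    per_recall = np.full(N_CLASSES, np.nan)
    per_precision = np.full(N_CLASSES, np.nan)
    per_label_acc = np.empty(N_CLASSES)
    for l in range(N_CLASSES):
        has_true = truth[:, l] > 0
        has_pred = pred[:, l] > 0
        if has_true.any():
            per_recall[l] = points[has_true].mean()
        else:
            log.info("class %d never true in the test set; skipped in recall", l + 1)
        if has_pred.any():
            per_precision[l] = points[has_pred].mean()
        else:
            log.info("class %d never predicted; skipped in precision", l + 1)
        per_label_acc[l] = (has_pred == has_true).mean()

    recall = float(np.nanmean(per_recall)) if not np.all(np.isnan(per_recall)) else 0.0
    precision = (float(np.nanmean(per_precision))
                 if not np.all(np.isnan(per_precision)) else 0.0)
    return MetricsReport(
        subset_accuracy=subset_accuracy,
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        average_label_accuracy=float(per_label_acc.mean()),
        per_label_accuracy=per_label_acc,
        per_label_recall=per_recall,
        per_label_precision=per_precision,
    )


def tune_threshold(
    val_scores: np.ndarray,
    val_truth: np.ndarray,
    grid_lo: float = -2.0,
    grid_hi: float = 2.0,
    step: float = 0.1,
    guarantee: bool = True,
) -> float:
    """Grid-search the decision threshold maximising subset accuracy.

    Ties break to the smallest grid value.
    """
    val_scores = np.atleast_2d(np.asarray(val_scores, float))
    val_truth = np.atleast_2d(np.asarray(val_truth, float))
    if val_scores.shape[0] == 0:
        raise ValueError("empty validation set")
    n_steps = int(round((grid_hi - grid_lo) / step))
    if n_steps < 0:
        raise ValueError("empty threshold grid")
    grid = grid_lo + step * np.arange(n_steps + 1)
    best_t, best_acc = grid[0], -1.0
    for t in grid:
        pred = decide(val_scores, t, guarantee=guarantee)
        acc = compute_metrics(pred, val_truth).subset_accuracy
        if acc > best_acc:
            best_t, best_acc = t, acc
    return float(best_t)
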