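"""Confusion-matrix metrics, ROC/AUC, stratified k-fold CV, and printed-
metric confusion-matrix recovery.

The positive class is "pneumonia" throughout.  Metrics with an empty
denominator are reported as ``None`` (undefined), never silently zero.
``recover_confusion`` inverts published two-decimal metric values back to
the unique integer confusion matrix by exhaustive search, treating the
printed numbers as truncations (not roundings) of the exact fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .fixtures import DatasetManifest

POSITIVE_CLASS = "pneumonia"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix entries must be >= 0")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.positives + self.negatives


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    specificity: float | None
    auc: float | None = None

    def as_percentages(self) -> dict[str, float | None]:
        out = {}
        for name in ("accuracy", "precision", "recall", "f1", "specificity"):
            value = getattr(self, name)
            out[name] = None if value is None else value * 100.0
        out["auc"] = self.auc
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 and specificity from TP/FN/FP/TN."""
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    return MetricsReport(accuracy, precision, recall, f1, specificity)


def confusion_from_predictions(y_true: list[str], y_pred: list[str],
                               positive: str = POSITIVE_CLASS
                               ) -> ConfusionMatrix:
    tp = sum(1 for t, p in zip(y_true, y_pred)
             if t == positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred)
             if t == positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred)
             if t != positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred)
             if t != positive and p != positive)
    return ConfusionMatrix(tp, fn, fp, tn)


# ----------------------------------------------------------------------
def auc_from_scores(pos_scores, neg_scores) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Equals the trapezoidal area under the empirical ROC curve.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes need at least one score")
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[:pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ----------------------------------------------------------------------
def stratified_kfold(manifest: DatasetManifest, k: int = 5, seed: int = 0
                     ) -> list[tuple[DatasetManifest, DatasetManifest]]:
    """Split a manifest into k stratified (train, val) manifest pairs."""
    labels = manifest.labels()
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    for lab, count in counts.items():
        if count < k:
            raise ValueError(f"class {lab!r} has {count} samples, fewer "
                             f"than k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in splitter.split(np.zeros(len(labels)), labels):
        folds.append((manifest.subset(train_idx), manifest.subset(val_idx)))
    return folds


# ----------------------------------------------------------------------
def truncate_2dp(fraction: float) -> float:
    """Truncate a fraction to a 2-d.p. percentage (93.846% -> 93.84)."""
    return np.floor(fraction * 10000.0) / 100.0


class RecoveryError(ValueError):
    pass


def recover_confusion(n_pos: int, n_neg: int, printed_accuracy: float,
                      printed_recall: float) -> ConfusionMatrix:
    """Recover the integer confusion matrix behind printed 2-d.p. metrics.

    Exhaustive search over TP in [0, n_pos] and TN in [0, n_neg] for
    matrices whose accuracy and recall, truncated to two decimal places
    (as percentages), equal the printed values.  Raises ``RecoveryError``
    if no matrix or more than one matrix is consistent.
    """
    tp = np.arange(n_pos + 1)
    recall_ok = tp[np.floor(tp / n_pos * 10000.0) / 100.0 == printed_recall]
    total = n_pos + n_neg
    solutions = []
    tn = np.arange(n_neg + 1)
    for tp_val in recall_ok:
        acc = np.floor((tp_val + tn) / total * 10000.0) / 100.0
        for tn_val in tn[acc == printed_accuracy]:
            solutions.append(ConfusionMatrix(
                tp=int(tp_val), fn=int(n_pos - tp_val),
                fp=int(n_neg - tn_val), tn=int(tn_val)))
    if not solutions:
        raise RecoveryError(
            f"no confusion matrix with n_pos={n_pos}, n_neg={n_neg} "
            f"truncates to accuracy {printed_accuracy} and recall "
            f"{printed_recall}")
    if len(solutions) > 1:
        raise RecoveryError(
            f"{len(solutions)} matrices are consistent with the printed "
            f"values: {solutions}")
    return solutions[0]


# ----------------------------------------------------------------------
@dataclass
class CVResult:
    folds: list[MetricsReport]
    k: int
    seed: int

    def mean_std(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in ("accuracy", "precision", "recall", "f1", "specificity",
                     "auc"):
            values = [getattr(r, name) for r in self.folds
                      if getattr(r, name) is not None]
            if values:
                out[name] = (float(np.mean(values)), float(np.std(values)))
        return out
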