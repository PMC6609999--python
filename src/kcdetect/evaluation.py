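"""Detector evaluation: confusion metrics, cross-validation, ROC, event matching.

Segment-level metrics from the confusion table (TP, FP, TN, FN):

    ACC = (TP + TN) / N            SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)           FPR = FP / (FP + TN) = 1 - SPE
    MCC = (TP·TN - FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F   = 2·TP / (2·TP + FP + FN)
    kappa = (ACC - pre) / (1 - pre),
        pre = p1·q1 + (1-p1)·(1-q1),  p1 = (TP+FN)/N,  q1 = (TP+FP)/N

Metrics whose denominator vanishes are reported as NaN ("undefined"), never
silently coerced to 0.

Cross-validated performance is the arithmetic mean of the per-fold
accuracies over a stratified k-fold split (default k = 6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io import EventAnnotation

__all__ = [
    "ConfusionTable",
    "CVResult",
    "confusion",
    "metrics",
    "stratified_folds",
    "kfold_cv",
    "roc_auc",
    "match_events",
]


@dataclass(frozen=True)
class ConfusionTable:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    fold_assignments: np.ndarray  # per-sample test-fold index


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionTable:
    """Count the four confusion cells for binary 0/1 labels."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(truth)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    return ConfusionTable(
        TP=int(np.sum((pred == 1) & (truth == 1))),
        FP=int(np.sum((pred == 1) & (truth == 0))),
        TN=int(np.sum((pred == 0) & (truth == 0))),
        FN=int(np.sum((pred == 0) & (truth == 1))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def metrics(t: ConfusionTable) -> dict[str, float]:
    """All scalar metrics of one confusion table; undefined entries are NaN."""
    if t.N == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = float(t.TP), float(t.FP), float(t.TN), float(t.FN)
    n = float(t.N)
    acc = (tp + tn) / n
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    p1 = (tp + fn) / n
    q1 = (tp + fp) / n
    pre = p1 * q1 + (1 - p1) * (1 - q1)
    return {
        "ACC": acc,
        "SEN": _ratio(tp, tp + fn),
        "SPE": _ratio(tn, tn + fp),
        "FPR": _ratio(fp, fp + tn),
        "MCC": _ratio(tp * tn - fp * fn, mcc_den),
        "F": _ratio(2 * tp, 2 * tp + fp + fn),
        "kappa": _ratio(acc - pre, 1 - pre),
    }


def stratified_folds(y: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment: per-class shuffle, round-robin deal."""
    y = np.asarray(y)
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def kfold_cv(
    X: np.ndarray,
    y: Sequence[int],
    classifier: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    k: int = 6,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation (default 6 folds).

    Parameters
    ----------
    classifier : callable
        ``classifier(X_train, y_train, X_test) -> predicted labels``.

    Returns
    -------
    CVResult
        Per-fold accuracies, their arithmetic mean, and the fold index of
        every sample (each sample is tested exactly once).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = stratified_folds(y, k, seed)
    accs = []
    for f in range(k):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f}: a class is absent from the training split")
        pred = np.asarray(classifier(X[train], y[train], X[test]))
        accs.append(float(np.mean(pred == y[test])))
    accs = np.array(accs)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        fold_assignments=folds,
    )


def roc_auc(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over all score thresholds) and trapezoid AUC.

    Tied scores are collapsed into one curve vertex, which is equivalent to
    rank averaging; all-identical scores therefore give AUC 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in truth")
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(t)[distinct]
    fps = np.cumsum(1 - t)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def match_events(
    detections: list[EventAnnotation], references: list[EventAnnotation]
) -> tuple[int, int, int]:
    """Event-level scoring: greedy one-to-one matching by descending overlap.

    Each reference can absorb at most one detection. A detection overlapping
    no unmatched reference is a false positive; an unmatched reference is a
    false negative.

    Returns
    -------
    (TP, FP, FN)
    """
    overlaps = []
    for di, det in enumerate(detections):
        for ri, ref in enumerate(references):
            ov = min(det.end, ref.end) - max(det.onset, ref.onset)
            if ov > 0:
                overlaps.append((ov, di, ri))
    overlaps.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_d: set[int] = set()
    matched_r: set[int] = set()
    tp = 0
    for _, di, ri in overlaps:
        if di in matched_d or ri in matched_r:
            continue
        matched_d.add(di)
        matched_r.add(ri)
        tp += 1
    fp = len(detections) - tp
    fn = len(references) - tp
    return tp, fp, fn
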