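"""10-fold cross-validation with balanced/unbalanced negative sampling, and
the four evaluation metrics (AUC, AUPR, F1, MCC) plus their average.

Folds split *pairs* (edge-wise CV): the positives are shuffled and dealt
round-robin into k test sets.  In unbalanced mode every non-positive pair
is used, each appearing in exactly one fold's test negatives; in balanced
mode each fold samples as many negatives as it has positives, without
replacement, preferring explicitly 0-labelled pairs over unknown ones.

Metric conventions, fixed so results are reproducible bit-for-bit:
AUC is the rank statistic (ties count 0.5); AUPR is average precision
(step-curve, no trapezoidal interpolation); F1 and MCC come from the
confusion matrix at the configured threshold, with MCC defined as 0 when
its denominator vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .config import TrainConfig
from .data_io import AssociationMatrix
from .errors import FoldError, MetricError
from .model import encode, score
from .training import TrainHistory, train_model

__all__ = ["FoldSplit", "MetricsReport", "make_folds", "compute_metrics",
           "run_fold", "cross_validate"]

Mode = Literal["balanced", "unbalanced"]

Pair = tuple[int, int]


@dataclass
class FoldSplit:
    """Train/test positive and negative index pairs of one CV fold."""

    fold_id: int
    train_pos: set[Pair]
    test_pos: set[Pair]
    train_neg: set[Pair]
    test_neg: set[Pair]
    mode: Mode


@dataclass
class MetricsReport:
    auc: float
    aupr: float
    f1: float
    mcc: float
    n_pos: int
    n_neg: int
    threshold: float

    @property
    def average_metric(self) -> float:
        return (self.auc + self.aupr + self.f1 + self.mcc) / 4.0

    def to_dict(self) -> dict:
        return {"auc": self.auc, "aupr": self.aupr, "f1": self.f1,
                "mcc": self.mcc, "average_metric": self.average_metric,
                "n_pos": self.n_pos, "n_neg": self.n_neg,
                "threshold": self.threshold}


# ---------------------------------------------------------------------------
# folds

def make_folds(matrix: AssociationMatrix, k: int = 10,
               mode: Mode = "balanced", seed: int = 0) -> list[FoldSplit]:
    """Deal positives round-robin into k test sets and assign negatives.

    Explicitly 0-labelled pairs are sampled before unknown pairs in
    balanced mode.
    """
    if mode not in ("balanced", "unbalanced"):
        raise FoldError(f"unknown mode {mode!r}")
    positives = matrix.positives()
    if k < 2 or k > len(positives):
        raise FoldError(
            f"cannot build {k} folds from {len(positives)} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    shuffled = [positives[i] for i in order]
    test_pos_sets = [set(shuffled[f::k]) for f in range(k)]
    all_pos = set(positives)

    zero_pairs = [(i, j) for i in range(matrix.m) for j in range(matrix.n)
                  if matrix.A[i, j] == 0]
    known_neg = sorted(matrix.known_negatives)
    unknown = [p for p in zero_pairs if p not in matrix.known_negatives]

    folds: list[FoldSplit] = []
    if mode == "unbalanced":
        neg_order = rng.permutation(len(zero_pairs))
        neg_shuffled = [zero_pairs[i] for i in neg_order]
        test_neg_sets = [set(neg_shuffled[f::k]) for f in range(k)]
        all_neg = set(zero_pairs)
        for f in range(k):
            folds.append(FoldSplit(
                fold_id=f,
                train_pos=all_pos - test_pos_sets[f],
                test_pos=test_pos_sets[f],
                train_neg=all_neg - test_neg_sets[f],
                test_neg=test_neg_sets[f],
                mode=mode))
        return folds

    # balanced: per fold, sample |train_pos| + |test_pos| negatives without
    # replacement, known negatives first
    for f in range(k):
        test_pos = test_pos_sets[f]
        train_pos = all_pos - test_pos
        need = len(train_pos) + len(test_pos)
        if need > len(zero_pairs):
            raise FoldError("not enough non-positive pairs for balanced mode")
        pool = known_neg + [unknown[i]
                            for i in rng.permutation(len(unknown))]
        chosen = pool[:need]
        chosen = [chosen[i] for i in rng.permutation(len(chosen))]
        test_neg = set(chosen[: len(test_pos)])
        train_neg = set(chosen[len(test_pos):])
        folds.append(FoldSplit(fold_id=f, train_pos=train_pos,
                               test_pos=test_pos, train_neg=train_neg,
                               test_neg=test_neg, mode=mode))
    return folds


# ---------------------------------------------------------------------------
# metrics

def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC; tied scores contribute 1/2."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def _average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP = sum_i (R_i - R_{i-1}) P_i over descending unique score thresholds."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # collapse tied scores: keep the last index of each tie block
    last_of_block = np.r_[s[1:] != s[:-1], True]
    tp = tp[last_of_block]
    fp = fp[last_of_block]
    precision = tp / (tp + fp)
    recall = tp / labels.sum()
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def compute_metrics(scores: Sequence[float], labels: Sequence[int],
                    threshold: float = 0.5) -> MetricsReport:
    """AUC, AUPR, F1 and MCC of a score vector against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError("scores and labels must be equal-length vectors")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("metrics undefined for single-class labels")

    auc = _auc_rank(scores, labels)
    aupr = _average_precision(scores, labels)

    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    return MetricsReport(auc=auc, aupr=aupr, f1=float(f1), mcc=float(mcc),
                         n_pos=n_pos, n_neg=n_neg, threshold=threshold)


# ---------------------------------------------------------------------------
# cross-validation

def _evaluate_pairs(score_matrix: np.ndarray, pos: set[Pair], neg: set[Pair],
                    threshold: float) -> tuple[np.ndarray, np.ndarray]:
    pairs = sorted(pos) + sorted(neg)
    s = np.array([score_matrix[i, j] for i, j in pairs])
    y = np.array([1] * len(pos) + [0] * len(neg))
    return s, y


def run_fold(matrix: AssociationMatrix, fold: FoldSplit,
             config: TrainConfig) -> tuple[MetricsReport, TrainHistory,
                                           np.ndarray, np.ndarray]:
    """Train and evaluate one fold.

    The fold's test positives are zeroed in a training copy of the matrix
    *before* similarity construction, so no test label can leak into the
    kernel or the loss.
    """
    train_matrix = matrix.copy()
    for i, j in fold.test_pos:
        train_matrix.A[i, j] = 0.0
    train_mask = sorted(fold.train_pos | fold.train_neg)
    params, history = train_model(train_matrix, train_mask, config)
    Xl, Xd = encode(train_matrix, config, params)
    S = score(Xl, Xd)
    s, y = _evaluate_pairs(S, fold.test_pos, fold.test_neg, config.threshold)
    return compute_metrics(s, y, config.threshold), history, s, y


def cross_validate(matrix: AssociationMatrix, config: TrainConfig,
                   k: int = 10, mode: Mode = "balanced",
                   callback=None) -> dict:
    """Run k-fold CV: per fold, zero the test positives, recompute
    similarity, train, score, and evaluate on the fold's test pairs.

    Returns per-fold reports, a fold-mean/std summary, and pooled metrics
    computed on all folds' test predictions concatenated (both aggregations
    are reported since either may be wanted).
    """
    folds = make_folds(matrix, k=k, mode=mode, seed=config.seed)
    reports: list[MetricsReport] = []
    histories: list[TrainHistory] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold in folds:
        report, history, s, y = run_fold(matrix, fold, config)
        reports.append(report)
        histories.append(history)
        pooled_scores.append(s)
        pooled_labels.append(y)
        if callback is not None:
            callback(fold.fold_id, report)

    names = ("auc", "aupr", "f1", "mcc", "average_metric")
    summary = {}
    for name in names:
        vals = [getattr(r, name) for r in reports]
        summary[name] = {"mean": float(np.mean(vals)),
                         "std": float(np.std(vals))}
    pooled = compute_metrics(np.concatenate(pooled_scores),
                             np.concatenate(pooled_labels), config.threshold)
    return {"folds": [r.to_dict() for r in reports],
            "summary": summary,
            "pooled": pooled.to_dict(),
            "histories": histories,
            "k": k, "mode": mode}
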