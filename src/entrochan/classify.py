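"""KNN emotion classification with ten-fold cross-validation.

The classifier is deliberately implemented from first principles rather than
wrapped from a library, because its tie-breaking contract is part of the
method: with K = 2 a split vote falls back to the single nearest neighbour's
label, and equidistant neighbours at the K-boundary are admitted by lowest
training-row index (stable sort), so every prediction is deterministic.
Folds are random, not stratified: class imbalance in the data propagates
into the fold composition exactly as it would in the original protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import FeatureTable

__all__ = ["KNNConfig", "CVResult", "knn_predict", "cross_validate",
           "confusion_matrix", "fold_partition"]


@dataclass(frozen=True)
class KNNConfig:
    """K, distance metric and the seed used for fold shuffling."""

    k: int = 2
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")


@dataclass
class CVResult:
    """Per-fold accuracies, their mean and a row-normalised confusion matrix."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    confusion: pd.DataFrame
    predictions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if not np.isclose(self.mean_accuracy, self.fold_accuracies.mean()):
            raise ValueError("mean_accuracy inconsistent with folds")


def knn_predict(train_x: np.ndarray, train_labels: np.ndarray,
                test_x: np.ndarray, cfg: KNNConfig = KNNConfig()) -> np.ndarray:
    """Predict labels for ``test_x`` by majority vote of the K nearest rows.

    Ties in the vote fall back to the tied label whose representative is
    nearest (for K = 2 this is the single nearest neighbour's label).
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_labels = np.asarray(train_labels, dtype=object)
    if len(train_x) == 0:
        raise ValueError("empty training set")
    if cfg.k > len(train_x):
        raise ValueError(f"K={cfg.k} exceeds training size {len(train_x)}")
    if train_x.shape[1] != test_x.shape[1]:
        raise ValueError("feature dimension mismatch")

    dist = cdist(test_x, train_x, metric="euclidean")
    order = np.argsort(dist, axis=1, kind="stable")
    out = np.empty(len(test_x), dtype=object)
    for i in range(len(test_x)):
        nn = order[i, : cfg.k]
        votes: dict[object, int] = {}
        for j in nn:
            votes[train_labels[j]] = votes.get(train_labels[j], 0) + 1
        top = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == top]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            # nearest representative among the tied labels
            for j in nn:
                if train_labels[j] in tied:
                    out[i] = train_labels[j]
                    break
    return out


def fold_partition(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Shuffle row indices once and split into near-equal folds."""
    if n < folds:
        raise ValueError(f"{n} rows cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate(table: FeatureTable, cfg: KNNConfig = KNNConfig(),
                   folds: int = 10,
                   partition: list[np.ndarray] | None = None) -> CVResult:
    """Ten-fold (by default) cross-validated KNN accuracy.

    Rows are shuffled once with ``cfg.seed`` and split into near-equal folds;
    each fold serves once as the test set.  A precomputed ``partition`` may
    be supplied to hold folds fixed across channel-set comparisons.
    """
    x = table.matrix()
    y = table.labels
    if partition is None:
        partition = fold_partition(len(x), folds, cfg.seed)
    if any(len(p) == 0 for p in partition):
        raise ValueError("a fold has zero rows")
    accs = []
    preds = np.empty(len(x), dtype=object)
    all_idx = np.arange(len(x))
    for test_idx in partition:
        train_mask = np.ones(len(x), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        p = knn_predict(x[train_idx], y[train_idx], x[test_idx], cfg)
        preds[test_idx] = p
        accs.append(float(np.mean(p == y[test_idx])))
    accs = np.asarray(accs)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        confusion=confusion_matrix(y, preds),
        predictions=preds,
    )


def confusion_matrix(true_labels, predicted_labels) -> pd.DataFrame:
    """Row-normalised percentage confusion matrix.

    Entry (i, j) is 100 x P(predicted = j | true = i).  Classes appearing
    only in the predictions get a column; classes with zero true rows get a
    NaN-free all-zero row and are recorded in ``df.attrs['empty_classes']``.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    classes = sorted(set(true_labels) | set(predicted_labels), key=str)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=float)
    for t, p in zip(true_labels, predicted_labels):
        counts.loc[t, p] += 1
    row_sums = counts.sum(axis=1)
    empty = [c for c in classes if row_sums[c] == 0]
    pct = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    pct = pct.fillna(0.0)
    pct.attrs["empty_classes"] = empty
    return pct
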