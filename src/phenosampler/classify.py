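"""Nearest-neighbour classification accuracy — the likelihood engine.

Every sampler scores a candidate gene network by the accuracy of a k-NN
classifier restricted to that network's genes: leave-one-out cross-validation
when train and test coincide, blind prediction of held-out samples otherwise.
Accuracy is reported as a percentage, 100 minus the percentage of
misclassified samples.

All tie rules are deterministic: equidistant neighbours are resolved toward
the smallest training-sample index, and (for even vote splits, which cannot
occur with odd k and two classes) votes resolve toward class 1.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .core import AccuracyResult
from .datasets import ExpressionDataset

__all__ = ["loocv_accuracy", "blind_validation_accuracy", "loocv_prefix_profile"]


def _knn_vote(sq_dists: np.ndarray, train_labels: np.ndarray, k: int) -> np.ndarray:
    """Predict one class per row of a (test x train) squared-distance matrix.

    Stable argsort makes the k-neighbour set deterministic under distance
    ties (smallest training index wins); ``>=`` in the vote sends exact vote
    ties to class 1.
    """
    if k == 1:
        nearest = np.argmin(sq_dists, axis=1)  # first occurrence = smallest index
        return train_labels[nearest]
    order = np.argsort(sq_dists, axis=1, kind="stable")[:, :k]
    votes1 = (train_labels[order] == 1).sum(axis=1)
    return np.where(votes1 >= k - votes1, 1, 2)


def loocv_accuracy(
    dataset: ExpressionDataset, signature: list[int] | np.ndarray, k: int = 1
) -> AccuracyResult:
    """Leave-one-out accuracy of a k-NN classifier on the signature's genes.

    Each sample is predicted from its k nearest neighbours (Euclidean
    distance over the signature genes) among all *other* samples.
    """
    sig = np.asarray(signature, dtype=np.int64)
    if sig.size == 0:
        raise ValueError("signature must be nonempty")
    n = dataset.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    X = dataset.values[sig].T  # samples x genes
    D = cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(D, np.inf)
    pred = _knn_vote(D, dataset.labels, k)
    wrong = np.flatnonzero(pred != dataset.labels)
    return AccuracyResult(
        accuracy=100.0 * (n - wrong.size) / n,
        n_evaluated=n,
        misclassified_sample_ids=[dataset.sample_ids[i] for i in wrong],
    )


def blind_validation_accuracy(
    train: ExpressionDataset,
    valid: ExpressionDataset,
    signature: list[int] | np.ndarray,
    k: int = 1,
) -> AccuracyResult:
    """Accuracy on held-out samples predicted from training samples only.

    Validation labels are used exclusively to score the predictions, never to
    make them, so the evaluation is leakage-free.
    """
    sig = np.asarray(signature, dtype=np.int64)
    if sig.size == 0:
        raise ValueError("signature must be nonempty")
    if valid.n_samples == 0:
        raise ValueError("validation set is empty")
    if train.probe_ids != valid.probe_ids:
        raise ValueError("train and validation sets must share the same probe space")
    if k >= train.n_samples:
        raise ValueError(f"k={k} must be smaller than the number of training samples")
    D = cdist(valid.values[sig].T, train.values[sig].T, metric="sqeuclidean")
    pred = _knn_vote(D, train.labels, k)
    wrong = np.flatnonzero(pred != valid.labels)
    return AccuracyResult(
        accuracy=100.0 * (valid.n_samples - wrong.size) / valid.n_samples,
        n_evaluated=valid.n_samples,
        misclassified_sample_ids=[valid.sample_ids[i] for i in wrong],
    )


def loocv_prefix_profile(
    values: np.ndarray, labels: np.ndarray, ranked_genes: np.ndarray, k: int = 1
) -> np.ndarray:
    """LOOCV accuracy for every nested prefix of a ranked gene list.

    Exploits the fact that squared Euclidean distance over a prefix of length
    L+1 is the length-L distance plus one gene's contribution, so the whole
    profile costs O(L n^2) instead of O(L^2 n^2).  Returns accuracies (percent)
    for prefix lengths 1..len(ranked_genes).
    """
    n = values.shape[1]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    D = np.zeros((n, n))
    profile = np.empty(len(ranked_genes))
    diag = np.arange(n)
    for i, g in enumerate(ranked_genes):
        x = values[g]
        D += (x[:, None] - x[None, :]) ** 2
        Dwork = D.copy()
        Dwork[diag, diag] = np.inf
        pred = _knn_vote(Dwork, labels, k)
        profile[i] = 100.0 * np.mean(pred == labels)
    return profile
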