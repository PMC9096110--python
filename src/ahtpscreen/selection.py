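"""Feature selection: ReliefF relevance filtering and recursive feature
elimination (RFE).

ReliefF scores a feature by how much it separates each instance from its
k nearest misses (other class) relative to its k nearest hits (same class);
features that differ across nearby class boundaries but agree within a
class get high weights. Weights of min-max-scaled features lie in [-1, 1].
Neighbor search uses Manhattan distance on the scaled features, ties broken
by instance index.

RFE wraps an estimator with per-feature importances: it repeatedly drops
the ``step`` least important features and refits until ``target_k``
features remain. For a linear SVM the importance is the squared weight; for
the RBF-kernel SVM (no native per-feature weights) a permutation-importance
mode on a held-out fold is provided.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC, LinearSVC


@dataclass
class FeatureScores:
    """Per-feature ReliefF weights with ranking."""

    names: tuple[str, ...]
    weights: np.ndarray
    cutoff: float | None = None

    @property
    def ranking(self) -> np.ndarray:
        """Feature indices from best to worst; ties broken by schema order."""
        return np.lexsort((np.arange(len(self.weights)), -self.weights))

    def to_tsv(self, path, cutoff: float | None = None) -> None:
        cut = self.cutoff if cutoff is None else cutoff
        rank_of = np.empty(len(self.weights), dtype=int)
        rank_of[self.ranking] = np.arange(1, len(self.weights) + 1)
        with open(path, "w") as fh:
            fh.write("feature\tweight\trank\tkept\n")
            for i, n in enumerate(self.names):
                kept = "" if cut is None else int(self.weights[i] > cut)
                fh.write(f"{n}\t{self.weights[i]:.6g}\t{rank_of[i]}\t{kept}\n")


def _minmax(X: np.ndarray) -> np.ndarray:
    lo, hi = X.min(0), X.max(0)
    span = hi - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def relieff_scores(X: np.ndarray, y: np.ndarray, names=None,
                   k_neighbors: int = 10, n_samples: int | None = None,
                   seed: int = 0) -> FeatureScores:
    """Standard ReliefF weights for a binary-labeled matrix.

    ``n_samples`` limits the number of instances whose neighborhoods are
    evaluated (None = all); sampling and all arithmetic are deterministic
    given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < k_neighbors + 1:
        raise ValueError(
            f"every class needs >= k_neighbors+1={k_neighbors + 1} instances; "
            f"smallest has {counts.min()}")
    n, p = X.shape
    names = tuple(names) if names is not None else tuple(f"f{i}" for i in range(p))
    Xs = _minmax(X)

    rng = np.random.default_rng(seed)
    if n_samples is None or n_samples >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = np.sort(rng.choice(n, size=n_samples, replace=False))

    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    nn_by_class = {}
    idx_by_class = {}
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx_by_class[c] = idx
        nn_by_class[c] = NearestNeighbors(metric="manhattan").fit(Xs[idx])

    weights = np.zeros(p)
    m = len(sample_idx)
    for i in sample_idx:
        xi = Xs[i:i + 1]
        ci = y[i]
        for c in classes:
            # same class: skip self, so query one extra neighbor
            extra = 1 if c == ci else 0
            _, nbr = nn_by_class[c].kneighbors(xi, n_neighbors=k_neighbors + extra)
            nbr_idx = idx_by_class[c][nbr[0]]
            if extra:
                nbr_idx = nbr_idx[nbr_idx != i][:k_neighbors]
            diffs = np.abs(Xs[nbr_idx] - Xs[i]).mean(0)
            if c == ci:
                weights -= diffs / m
            else:
                factor = priors[c] / (1.0 - priors[ci])
                weights += factor * diffs / m
    return FeatureScores(names=names, weights=weights)


def apply_cutoff(scores: FeatureScores, cutoff: float | None = 0.0,
                 top_n: int | None = None) -> list[int]:
    """Indices of retained features, in schema (column) order.

    Either keep features with weight strictly above ``cutoff`` or the
    ``top_n`` best-ranked (ties broken by schema order).
    """
    if top_n is not None:
        if top_n < 0 or top_n > len(scores.weights):
            raise ValueError("top_n out of range")
        keep = np.sort(scores.ranking[:top_n])
    else:
        keep = np.flatnonzero(scores.weights > cutoff)
    if keep.size == 0:
        raise ValueError("cutoff removed every feature")
    return keep.tolist()


def _standardize(X: np.ndarray) -> np.ndarray:
    mu, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def linear_svm_importance(estimator, X, y, seed=0) -> np.ndarray:
    """Squared weights of a linear SVM fitted on standardized features."""
    est = clone(estimator)
    est.fit(_standardize(X), y)
    return np.ravel(est.coef_) ** 2


def permutation_importance_rbf(estimator, X, y, seed=0,
                               val_fraction: float = 0.25) -> np.ndarray:
    """Permutation importance of an RBF SVM on a held-out validation fold."""
    X = _standardize(X)
    Xtr, Xval, ytr, yval = train_test_split(
        X, y, test_size=val_fraction, random_state=seed, stratify=y)
    est = clone(estimator)
    est.fit(Xtr, ytr)
    base = accuracy_score(yval, est.predict(Xval))
    rng = np.random.default_rng(seed)
    imp = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        Xp = Xval.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        imp[j] = base - accuracy_score(yval, est.predict(Xp))
    return imp


def rfe_select(X: np.ndarray, y: np.ndarray, estimator=None, step: int = 1,
               target_k: int | None = None, importance: str = "linear",
               seed: int = 0, _refit_counter: list | None = None) -> list[int]:
    """Recursive feature elimination; returns retained column indices in order.

    ``importance='linear'`` uses squared weights of a linear SVM surrogate
    (fast); ``'permutation'`` uses permutation importance of the given
    (RBF) estimator on a validation fold. The loop performs
    ceil((p - target_k)/step) refits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if target_k is None:
        target_k = max(1, p // 2)
    if target_k >= p:
        if target_k > p:
            import warnings
            warnings.warn(f"target_k={target_k} >= feature count {p}; "
                          "returning all features", stacklevel=2)
        return list(range(p))
    if estimator is None:
        estimator = (LinearSVC(dual="auto", random_state=seed, max_iter=5000,
                               tol=1e-3) if importance == "linear"
                     else SVC(kernel="rbf", C=36.0, gamma=0.119, random_state=seed))
    remaining = list(range(p))
    while len(remaining) > target_k:
        Xr = X[:, remaining]
        if importance == "linear":
            imp = linear_svm_importance(estimator, Xr, y, seed)
        elif importance == "permutation":
            imp = permutation_importance_rbf(estimator, Xr, y, seed)
        else:
            raise ValueError(f"unknown importance mode {importance!r}")
        if _refit_counter is not None:
            _refit_counter.append(len(remaining))
        n_drop = min(step, len(remaining) - target_k)
        # drop the n_drop least important; ties broken by column order
        order = np.lexsort((np.arange(len(remaining)), imp))
        drop = set(order[:n_drop])
        remaining = [f for j, f in enumerate(remaining) if j not in drop]
    return remaining


def expected_rfe_refits(p: int, k: int, step: int) -> int:
    return math.ceil(max(0, p - k) / step)
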