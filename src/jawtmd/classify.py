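"""The four classifier configurations under one train/predict contract.

The headline method is a native k-nearest-neighbour classifier with
Euclidean distance

    d(A, B) = sqrt( Σᵢ (Aᵢ − Bᵢ)² )

and k = 1 by default (implemented here, not delegated). Random Forest
(120 trees, bagged), Naïve Bayes (Gaussian, or per-feature normal-kernel
density — the reporting default) and a one-vs-one SVM (polynomial kernel,
degree 3 by default) are provided behind the same contract; RF, Gaussian NB
and SVM delegate to scikit-learn, the kernel-density NB is implemented here.

Determinism: ``train`` is a pure function of (config, X, y, seed) and
``predict`` of (model, X) — no hidden randomness at predict time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "PRESETS",
    "knn_predict",
    "train",
    "predict",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of one classifier.

    ``method`` is one of ``knn``, ``rf``, ``nb``, ``svm``; the remaining
    fields apply to their respective methods only. Defaults follow the
    best-performing settings of each method: k=1, 120 trees, normal-kernel
    NB, polynomial (degree-3) one-vs-one SVM.
    """

    method: str = "knn"
    k: int = 1
    n_trees: int = 120
    nb_density: str = "kernel_normal"  # or "gaussian"
    svm_kernel: str = "polynomial"  # or "linear", "gaussian"
    svm_degree: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("knn", "rf", "nb", "svm"):
            raise ValueError(f"unknown method: {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.nb_density not in ("gaussian", "kernel_normal"):
            raise ValueError(f"unknown nb_density: {self.nb_density!r}")
        if self.svm_kernel not in ("linear", "gaussian", "polynomial"):
            raise ValueError(f"unknown svm_kernel: {self.svm_kernel!r}")

    def describe(self) -> str:
        return {
            "knn": f"KNN (k={self.k})",
            "rf": f"Random Forest ({self.n_trees} trees)",
            "nb": f"Naive Bayes ({self.nb_density})",
            "svm": f"SVM ({self.svm_kernel}"
            + (f", degree {self.svm_degree})" if self.svm_kernel == "polynomial" else ")"),
        }[self.method]


#: the four reported configurations
PRESETS: dict[str, ClassifierConfig] = {
    "knn": ClassifierConfig(method="knn", k=1),
    "rf": ClassifierConfig(method="rf", n_trees=120),
    "nb": ClassifierConfig(method="nb", nb_density="kernel_normal"),
    "svm": ClassifierConfig(method="svm", svm_kernel="polynomial"),
}


def _as_matrix(X: Any) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    return X


def knn_predict(
    train_X: Any, train_y: Sequence, query_X: Any, k: int = 1
) -> np.ndarray:
    """k-nearest-neighbour prediction with Euclidean distance, majority vote.

    Ties in the vote are broken by the smaller mean neighbour distance, then
    by training-row order; equidistant neighbours at the k-boundary keep the
    earliest training rows (stable sort), so predictions are deterministic.
    """
    train_X = _as_matrix(train_X)
    query_X = _as_matrix(query_X)
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if train_y.shape[0] != train_X.shape[0]:
        raise ValueError("train_X and train_y length mismatch")
    if train_X.shape[1] != query_X.shape[1]:
        raise ValueError(
            f"feature-count mismatch: train has {train_X.shape[1]}, "
            f"query has {query_X.shape[1]}"
        )
    if k > train_X.shape[0]:
        raise ValueError(f"k={k} exceeds training size {train_X.shape[0]}")

    diffs = query_X[:, None, :] - train_X[None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=2))  # (n_query, n_train)

    out = []
    for row in dists:
        order = np.argsort(row, kind="stable")[:k]
        labels = train_y[order]
        candidates, counts = np.unique(labels, return_counts=True)
        best = candidates[counts == counts.max()]
        if len(best) == 1:
            out.append(best[0])
            continue
        # tie: smaller mean distance among the tied labels, then first seen
        means = {lab: row[order[labels == lab]].mean() for lab in best}
        min_mean = min(means.values())
        tied = [lab for lab in best if means[lab] == min_mean]
        if len(tied) == 1:
            out.append(tied[0])
        else:
            earliest = {lab: int(order[labels == lab].min()) for lab in tied}
            out.append(min(tied, key=lambda lab: earliest[lab]))
    return np.asarray(out)


class _KernelNaiveBayes:
    """Naïve Bayes with per-feature normal-kernel densities.

    Class-conditional densities are products of 1-D kernel density
    estimates with Gaussian kernels; the bandwidth follows the normal
    reference rule h = σ̂ (4 / 3n)^{1/5} per class and feature.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KernelNaiveBayes":
        self.classes_ = np.unique(y)
        self._train = {c: X[y == c] for c in self.classes_}
        self._bandwidth = {}
        self._log_prior = {}
        n_total = len(y)
        for c, Xc in self._train.items():
            n_c = Xc.shape[0]
            sd = Xc.std(axis=0, ddof=1) if n_c > 1 else np.zeros(Xc.shape[1])
            h = sd * (4.0 / (3.0 * n_c)) ** 0.2
            self._bandwidth[c] = np.maximum(h, 1e-9)  # guard constant features
            self._log_prior[c] = np.log(n_c / n_total)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.empty((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            Xc = self._train[c]  # (n_c, d)
            h = self._bandwidth[c]  # (d,)
            z = (X[:, None, :] - Xc[None, :, :]) / h  # (n, n_c, d)
            log_kernel = -0.5 * z**2 - np.log(h * np.sqrt(2 * np.pi))
            log_dens = logsumexp(log_kernel, axis=1) - np.log(Xc.shape[0])  # (n, d)
            scores[:, j] = log_dens.sum(axis=1) + self._log_prior[c]
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass
class TrainedModel:
    """Opaque fitted classifier plus its configuration."""

    config: ClassifierConfig
    n_features: int
    _impl: Any = field(repr=False)
    _train_X: np.ndarray | None = field(default=None, repr=False)
    _train_y: np.ndarray | None = field(default=None, repr=False)


def train(config: ClassifierConfig, X: Any, y: Sequence, seed: int = 0) -> TrainedModel:
    """Fit one classifier. Deterministic given (config, X, y, seed)."""
    X = _as_matrix(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")

    if config.method == "knn":
        return TrainedModel(config, X.shape[1], None, X.copy(), y.copy())
    if config.method == "rf":
        impl = RandomForestClassifier(
            n_estimators=config.n_trees, bootstrap=True, random_state=int(seed)
        ).fit(X, y)
    elif config.method == "nb":
        impl = (
            GaussianNB().fit(X, y)
            if config.nb_density == "gaussian"
            else _KernelNaiveBayes().fit(X, y)
        )
    elif config.method == "svm":
        kernel = {"linear": "linear", "gaussian": "rbf", "polynomial": "poly"}[
            config.svm_kernel
        ]
        # SVC trains one binary machine per class pair (one-vs-one)
        impl = SVC(kernel=kernel, degree=config.svm_degree, random_state=int(seed)).fit(X, y)
    else:  # pragma: no cover - config validation guards this
        raise ValueError(f"unknown method: {config.method!r}")
    return TrainedModel(config, X.shape[1], impl)


def predict(model: TrainedModel, X: Any) -> np.ndarray:
    """Predict labels for a query matrix sharing the training feature order."""
    X = _as_matrix(X)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature-count mismatch: model has {model.n_features}, query has {X.shape[1]}"
        )
    if model.config.method == "knn":
        return knn_predict(model._train_X, model._train_y, X, k=model.config.k)
    return np.asarray(model._impl.predict(X))
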