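"""One-vs-one multiclass SVM and the baseline classifiers.

For a k-class problem, k(k-1)/2 binary soft-margin SVMs are trained, one
per class pair; a sample is assigned the class with the most pairwise
votes (``f(x) = sgn(sum_i alpha_i y_i K(x_i, x) + b)`` per binary
machine).  Vote ties are broken by the largest aggregate signed decision
value, then lexicographically (with a warning).

The kernel menu is linear, cubic polynomial, RBF and sigmoid.  Baselines:
k-nearest neighbours (k=3, Euclidean), random forest (100 trees),
Gaussian naive Bayes and a decision tree.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

KERNELS = ("linear", "poly3", "rbf", "sigmoid")


def _binary_svc(kernel: str, C: float, gamma) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=C)
    if kernel == "poly3":
        return SVC(kernel="poly", degree=3, coef0=0.0, gamma=gamma, C=C)
    if kernel == "rbf":
        return SVC(kernel="rbf", gamma=gamma, C=C)
    if kernel == "sigmoid":
        return SVC(kernel="sigmoid", coef0=0.0, gamma=gamma, C=C)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


class OvoSvmClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-one SVM with explicit pairwise voting.

    Parameters
    ----------
    kernel : {'linear', 'poly3', 'rbf', 'sigmoid'}, default 'linear'
    C : float, default 1.0
        Soft-margin penalty (the toolbox default; not tuned).
    gamma : 'scale', 'auto' or float, default 'auto'
        Kernel coefficient for the non-linear kernels; 'auto' is 1/d.

    Attributes
    ----------
    classes_ : ndarray of class labels, lexicographically sorted.
    estimators_ : dict mapping class-index pairs (a, b), a < b, to the
        fitted binary SVC deciding between them.
    n_binary_classifiers_ : int, equal to k(k-1)/2.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0, gamma="auto"):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        self.classes_ = np.unique(y)
        k = len(self.classes_)
        if k < 2:
            raise ValueError(f"need at least 2 classes, got {k}")
        y_idx = np.searchsorted(self.classes_, y)
        self.estimators_ = {}
        for a, b in combinations(range(k), 2):
            mask = (y_idx == a) | (y_idx == b)
            clf = _binary_svc(self.kernel, self.C, self.gamma)
            # binary labels: -1 for class a, +1 for class b
            clf.fit(X[mask], np.where(y_idx[mask] == b, 1, -1))
            self.estimators_[(a, b)] = clf
        self.n_binary_classifiers_ = len(self.estimators_)
        self.n_features_in_ = X.shape[1]
        return self

    def _votes_and_margins(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was trained with "
                f"{self.n_features_in_}"
            )
        k = len(self.classes_)
        votes = np.zeros((X.shape[0], k))
        margins = np.zeros((X.shape[0], k))
        for (a, b), clf in self.estimators_.items():
            dec = clf.decision_function(X)  # >0 favours b
            votes[:, b] += dec > 0
            votes[:, a] += dec <= 0
            margins[:, b] += dec
            margins[:, a] -= dec
        return votes, margins

    def decision_function(self, X) -> np.ndarray:
        """Per-class vote counts (the OVO score used for ROC curves)."""
        votes, _ = self._votes_and_margins(X)
        return votes

    def predict(self, X) -> np.ndarray:
        votes, margins = self._votes_and_margins(X)
        winners = np.empty(votes.shape[0], dtype=int)
        warned = False
        for i in range(votes.shape[0]):
            top = np.flatnonzero(votes[i] == votes[i].max())
            if len(top) == 1:
                winners[i] = top[0]
                continue
            # tie: largest summed signed margin among tied classes
            sub = margins[i, top]
            best = np.flatnonzero(sub == sub.max())
            if len(best) > 1 and not warned:
                warnings.warn(
                    "vote and margin tie; resolving lexicographically", stacklevel=2
                )
                warned = True
            winners[i] = top[best[0]]
        return self.classes_[winners]


BASELINES = ("knn", "rf", "nb", "dt")


def make_classifier(kind: str = "svm", kernel: str = "linear", C: float = 1.0,
                    gamma="auto", seed: int = 0) -> BaseEstimator:
    """Instantiate a classifier by kind with the study's settings."""
    if kind == "svm":
        return OvoSvmClassifier(kernel=kernel, C=C, gamma=gamma)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=3, metric="euclidean")
    if kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "nb":
        return GaussianNB()
    if kind == "dt":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def class_scores(model: BaseEstimator, X) -> np.ndarray:
    """Per-class score matrix for ROC: OVO vote counts for the SVM,
    native class probabilities for the baselines."""
    if isinstance(model, OvoSvmClassifier):
        return model.decision_function(X)
    return model.predict_proba(np.asarray(X, dtype=float))


def train(X, y, kind: str = "svm", seed: int = 0, **params) -> BaseEstimator:
    """Fit a classifier of the given kind on (X, y)."""
    model = make_classifier(kind=kind, seed=seed, **params)
    return model.fit(np.asarray(X, dtype=float), np.asarray(y))


def predict(model: BaseEstimator, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class scores."""
    X = np.asarray(X, dtype=float)
    return model.predict(X), class_scores(model, X)


def clone_model(model: BaseEstimator) -> BaseEstimator:
    return clone(model)
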