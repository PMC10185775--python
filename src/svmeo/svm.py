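"""RBF-kernel soft-margin SVM with explicit one-vs-one multi-class voting.

The kernel is parameterised by a length-scale ("bandwidth") beta,
``K(x, y) = exp(-||x - y||^2 / (2 beta^2))``, so the optimizer's box
[0.001, 1000] for beta is interpreted on the scale of the (standardised)
features.  Each unordered class pair gets its own binary soft-margin SVM
(penalty weight alpha); multi-class predictions are decided by majority
vote with ties broken by the summed pairwise decision margin and then by
label order.  The per-class score is the vote fraction, a deterministic
quantity in [0, 1] summing to 1 per sample, used downstream for ROC/AUC
and Shapley attributions.

The pairwise quadratic programs are solved by scikit-learn's libsvm SMO
solver; voting, tie-breaking and scores are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = ["SVMHyperparams", "FittedSVM", "rbf_kernel", "rbf_gram", "fit_svm", "predict"]


@dataclass(frozen=True)
class SVMHyperparams:
    """Soft-margin penalty weight alpha and RBF bandwidth beta (both > 0)."""

    penalty: float
    bandwidth: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.penalty) and self.penalty > 0):
            raise ValueError(f"penalty must be a positive finite real, got {self.penalty}")
        if not (np.isfinite(self.bandwidth) and self.bandwidth > 0):
            raise ValueError(f"bandwidth must be a positive finite real, got {self.bandwidth}")

    @property
    def gamma(self) -> float:
        """Equivalent exponent coefficient, ``gamma = 1 / (2 beta^2)``."""
        return 1.0 / (2.0 * self.bandwidth**2)


def rbf_kernel(x: np.ndarray, y: np.ndarray, bandwidth: float) -> float:
    """Gaussian similarity ``exp(-||x - y||^2 / (2 beta^2))`` in (0, 1]."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * bandwidth**2)))


def rbf_gram(X: np.ndarray, Y: np.ndarray | None = None, bandwidth: float = 1.0) -> np.ndarray:
    """Kernel matrix K[i, j] = rbf_kernel(X[i], Y[j], bandwidth)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * bandwidth**2))


@dataclass
class FittedSVM:
    """A trained one-vs-one ensemble: one binary SVM per class pair."""

    class_labels: np.ndarray
    pairwise_models: dict
    training_feature_names: list
    hyperparams: SVMHyperparams

    @property
    def n_classes(self) -> int:
        return self.class_labels.size


def _as_matrix(features, feature_names: list | None) -> tuple[np.ndarray, list | None]:
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        if feature_names is not None and names != list(feature_names):
            raise ValueError(
                f"feature columns {names} do not match the expected order {list(feature_names)}"
            )
        return features.to_numpy(dtype=float), names
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X, feature_names


def fit_svm(
    features,
    labels,
    params: SVMHyperparams,
    feature_names: list | None = None,
) -> FittedSVM:
    """Train one binary soft-margin RBF SVM per unordered class pair.

    Raises if only one class is present or any feature value is missing.
    Class labels are kept in sorted order; predictions are restricted to
    the training label set.
    """
    X, names = _as_matrix(features, feature_names)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training requires at least 2 classes, got {classes.tolist()}")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    pairwise = {}
    for a, b in combinations(range(classes.size), 2):
        sel = (y == classes[a]) | (y == classes[b])
        clf = SVC(C=params.penalty, kernel="rbf", gamma=params.gamma)
        clf.fit(X[sel], y[sel])
        pairwise[(a, b)] = clf
    return FittedSVM(
        class_labels=classes,
        pairwise_models=pairwise,
        training_feature_names=list(names),
        hyperparams=params,
    )


def predict(model: FittedSVM, features) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-one voting over the pairwise models.

    Returns ``(labels, scores)`` where ``scores[i, k]`` is the fraction of
    pairwise votes sample i gave to class k (rows sum to 1).  Vote ties
    are broken by the larger summed signed decision margin, then by label
    order.
    """
    X, names = _as_matrix(features, model.training_feature_names)
    if names is not None and names != model.training_feature_names:
        raise ValueError("feature columns do not match the training schema")
    if X.shape[1] != len(model.training_feature_names):
        raise ValueError(
            f"expected {len(model.training_feature_names)} feature columns, got {X.shape[1]}"
        )
    n, k = X.shape[0], model.n_classes
    votes = np.zeros((n, k))
    margins = np.zeros((n, k))
    for (a, b), clf in model.pairwise_models.items():
        dec = clf.decision_function(X)
        # libsvm orders binary classes ascending: positive decision -> clf.classes_[1]
        hi = np.flatnonzero(model.class_labels == clf.classes_[1])[0]
        lo = np.flatnonzero(model.class_labels == clf.classes_[0])[0]
        votes[:, hi] += dec > 0
        votes[:, lo] += dec <= 0
        margins[:, hi] += dec
        margins[:, lo] -= dec
    n_pairs = len(model.pairwise_models)
    scores = votes / n_pairs
    # lexicographic argmax: votes, then margin, then label order
    order = np.lexsort(
        (np.arange(k)[None, :].repeat(n, axis=0), -margins, -votes), axis=1
    )
    winners = order[:, 0]
    labels = model.class_labels[winners]
    return labels, scores
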