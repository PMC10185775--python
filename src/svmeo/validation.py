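"""Participant-grouped stratified cross-validation and evaluation metrics.

Both eyes of a participant always land in the same fold, so test folds are
independent of training at the participant level; within each class,
participants are spread over folds as evenly as the counts allow.  Metrics
are per-class one-vs-rest sensitivity/specificity, overall accuracy, and
one-vs-rest ROC/AUC on the SVM vote-fraction scores, reported per fold and
as mean +/- SD across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import FeatureTable, Standardizer, standardize
from .svm import SVMHyperparams, fit_svm, predict

__all__ = [
    "FoldAssignment",
    "FoldMetrics",
    "CVReport",
    "make_folds",
    "confusion",
    "class_rates",
    "roc_auc",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    """Participant-level fold labels and the derived eye-level labels."""

    k: int
    participant_to_fold: dict
    eye_to_fold: dict

    def fold_of_eyes(self, eye_ids) -> np.ndarray:
        return np.array([self.eye_to_fold[e] for e in eye_ids])


def make_folds(
    table: FeatureTable, k: int = 5, rng: np.random.Generator | None = None
) -> FoldAssignment:
    """Randomly split participants into k folds, stratified by class.

    Within each class the participants are shuffled and dealt round-robin,
    so per-class participant counts per fold differ by at most one.  A
    participant whose eyes span classes (not produced by the generator,
    but possible in external tables) is stratified by its majority class.
    """
    if rng is None:
        rng = np.random.default_rng()
    df = table.data
    # majority class per participant, ties broken by label order
    part_class = (
        df.groupby("participant_id")["group"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
        .sort_index()
    )
    multi = df.groupby("participant_id")["group"].nunique()
    for pid in multi[multi > 1].index:
        logger.warning(
            "participant %s has eyes in multiple classes; stratifying by majority class %s",
            pid,
            part_class[pid],
        )
    participant_to_fold = {}
    for cls in np.unique(part_class.to_numpy()):
        members = part_class.index[part_class == cls].to_numpy()
        if members.size < k:
            raise ValueError(
                f"class {cls!r} has {members.size} participants; "
                f"at least {k} are required for {k}-fold grouped CV"
            )
        members = members[rng.permutation(members.size)]
        for i, pid in enumerate(members):
            participant_to_fold[pid] = i % k
    eye_to_fold = {
        eye: participant_to_fold[pid]
        for eye, pid in zip(df["eye_id"], df["participant_id"])
    }
    return FoldAssignment(k=k, participant_to_fold=participant_to_fold, eye_to_fold=eye_to_fold)


def confusion(true_labels, predicted_labels, class_order) -> np.ndarray:
    """Confusion matrix: entry (i, j) counts class-i samples predicted as j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    known = set(class_order)
    unknown = (set(true_labels) | set(predicted_labels)) - known
    if unknown:
        raise ValueError(f"labels {sorted(map(str, unknown))} not in class_order")
    return _sk_confusion(true_labels, predicted_labels, labels=list(class_order))


def class_rates(matrix: np.ndarray, class_index: int) -> tuple[float, float]:
    """One-vs-rest (sensitivity, specificity) for one class of a confusion matrix.

    A zero denominator yields NaN (undefined), never a silent 0.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = matrix[class_index, class_index]
    fn = matrix[class_index].sum() - tp
    fp = matrix[:, class_index].sum() - tp
    tn = matrix.sum() - tp - fn - fp
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(sensitivity), float(specificity)


def roc_auc(scores, true_labels, positive_class) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC curve and trapezoid AUC from per-class scores.

    Thresholds sweep the sorted unique scores with ties grouped, so the
    AUC equals the normalised Mann-Whitney U rank statistic.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels) == positive_class
    if y.all() or not y.any():
        raise ValueError(
            f"AUC for class {positive_class!r} is undefined: need both positive "
            "and negative examples"
        )
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    confusion: np.ndarray
    sensitivity: dict
    specificity: dict
    auc: dict
    accuracy: float
    n_test: int


@dataclass
class CVReport:
    """Per-fold metrics plus mean +/- SD aggregation across folds."""

    class_order: list
    per_fold: list
    failed_folds: list = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.per_fold])

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def pooled_confusion(self) -> np.ndarray:
        return np.sum([f.confusion for f in self.per_fold], axis=0)

    def tidy(self) -> pd.DataFrame:
        """One row per fold x class x metric, plus per-fold accuracy rows."""
        rows = []
        for f in self.per_fold:
            rows.append({"fold": f.fold, "class": "overall", "metric": "accuracy", "value": f.accuracy})
            for cls in self.class_order:
                for metric, store in (
                    ("sensitivity", f.sensitivity),
                    ("specificity", f.specificity),
                    ("auc", f.auc),
                ):
                    rows.append(
                        {"fold": f.fold, "class": cls, "metric": metric, "value": store[cls]}
                    )
        return pd.DataFrame(rows)

    def mean_sd(self) -> pd.DataFrame:
        """Across-fold mean and sample SD for every (class, metric) pair."""
        tidy = self.tidy()
        grouped = tidy.groupby(["class", "metric"])["value"]
        out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
        return out

    def to_dict(self) -> dict:
        return {
            "class_order": [str(c) for c in self.class_order],
            "per_fold": [
                {
                    "fold": f.fold,
                    "confusion": f.confusion.tolist(),
                    "sensitivity": {str(k): v for k, v in f.sensitivity.items()},
                    "specificity": {str(k): v for k, v in f.specificity.items()},
                    "auc": {str(k): v for k, v in f.auc.items()},
                    "accuracy": f.accuracy,
                    "n_test": f.n_test,
                }
                for f in self.per_fold
            ],
            "failed_folds": list(self.failed_folds),
            "mean_accuracy": self.mean_accuracy,
        }


def cross_validate(
    table: FeatureTable,
    feature_subset,
    params: SVMHyperparams,
    folds: FoldAssignment,
    standardization: str = "train_only",
) -> CVReport:
    """Grouped k-fold evaluation of one feature subset and hyperparameter pair.

    ``standardization='train_only'`` fits the z-score on each training split
    and applies it to the held-out fold (no leakage); ``'global'`` z-scores
    the whole table once before splitting.  A fold whose training split
    lacks a class is marked failed and excluded from the aggregation with
    a warning.
    """
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    if standardization not in ("train_only", "global"):
        raise ValueError("standardization must be 'train_only' or 'global'")

    work = table
    if standardization == "global":
        work, _ = standardize(table)
    X_all = work.data[feature_subset].to_numpy(dtype=float)
    y_all = work.y
    fold_of = folds.fold_of_eyes(work.eye_ids)
    class_order = list(np.unique(y_all))

    per_fold, failed = [], []
    for k in range(folds.k):
        test = fold_of == k
        train = ~test
        if set(np.unique(y_all[train])) != set(class_order) or not test.any():
            logger.warning("fold %d lacks a class in its training split; excluded", k)
            failed.append(k)
            continue
        X_tr, X_te = X_all[train], X_all[test]
        if standardization == "train_only":
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd[sd == 0] = 1.0  # constant-in-train column carries no signal
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model = fit_svm(X_tr, y_all[train], params, feature_names=feature_subset)
        pred, scores = predict(model, X_te)
        cm = confusion(y_all[test], pred, class_order)
        sens, spec, aucs = {}, {}, {}
        for i, cls in enumerate(class_order):
            sens[cls], spec[cls] = class_rates(cm, i)
            col = np.flatnonzero(model.class_labels == cls)[0]
            try:
                *_, aucs[cls] = roc_auc(scores[:, col], y_all[test], cls)
            except ValueError:
                aucs[cls] = float("nan")
        per_fold.append(
            FoldMetrics(
                fold=k,
                confusion=cm,
                sensitivity=sens,
                specificity=spec,
                auc=aucs,
                accuracy=float(np.trace(cm) / cm.sum()),
                n_test=int(test.sum()),
            )
        )
    return CVReport(class_order=class_order, per_fold=per_fold, failed_folds=failed)
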