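"""Model-agnostic Shapley attributions with exact enumeration.

Feature contributions to a model's per-class score are computed as exact
Shapley values of the coalition game

    v(S) = E_background[ f(x_S, B_{S complement}) ]

i.e. the marginal (interventional) expectation of the model output with
the coalition's features pinned to the explained instance and the rest
drawn from a background sample.  With the 4-6 feature subsets the wrapper
typically selects, all 2^M coalitions are enumerated, so the efficiency,
dummy and symmetry axioms hold to numerical precision; a permutation-
sampling estimator with standard errors covers larger masks.

The explained output is the per-class vote-fraction score of the fitted
one-vs-one SVM, evaluated on standardized features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ShapleyReport",
    "coalition_value",
    "exact_shapley",
    "sampled_shapley",
    "explain_table",
    "summarize",
    "force_decomposition",
    "svm_score_fn",
]

MAX_EXACT_FEATURES = 15


def svm_score_fn(model):
    """Wrap a FittedSVM into a batch score function X -> (n, n_classes)."""
    from .svm import predict

    def fn(X: np.ndarray) -> np.ndarray:
        _, scores = predict(model, np.asarray(X, dtype=float))
        return scores

    return fn


def coalition_value(
    score_fn, instance: np.ndarray, subset, background: np.ndarray
) -> np.ndarray:
    """Mean model score over the background with ``subset`` features pinned.

    ``subset`` indexes the features replaced by the explained instance's
    values; the empty subset returns the base value (mean background
    score) and the full subset returns the instance's own score.
    """
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D matrix")
    subset = np.asarray(list(subset), dtype=int)
    X = background.copy()
    if subset.size:
        X[:, subset] = np.asarray(instance, dtype=float)[subset]
    return np.asarray(score_fn(X)).mean(axis=0)


def _all_coalition_values(
    score_fn, instance: np.ndarray, background: np.ndarray, m: int
) -> np.ndarray:
    """Values v(S) for every bitmask S, batched into few model calls."""
    b = background.shape[0]
    n_sub = 1 << m
    batch, owners = [], []
    max_rows = 20000
    out = [None] * n_sub
    for s in range(n_sub):
        X = background.copy()
        idx = [j for j in range(m) if s >> j & 1]
        if idx:
            X[:, idx] = instance[idx]
        batch.append(X)
        owners.append(s)
        if len(batch) * b >= max_rows or s == n_sub - 1:
            scores = np.asarray(score_fn(np.vstack(batch)))
            scores = scores.reshape(len(batch), b, -1).mean(axis=1)
            for row, owner in zip(scores, owners):
                out[owner] = row
            batch, owners = [], []
    return np.vstack(out)


def exact_shapley(
    score_fn,
    instance: np.ndarray,
    background: np.ndarray,
    max_features: int = MAX_EXACT_FEATURES,
) -> np.ndarray:
    """Exact Shapley contributions, shape (n_features, n_classes).

    Enumerates all 2^M coalitions with the classic weights
    |S|! (M-|S|-1)! / M!.  Refuses M > ``max_features`` and points the
    caller to :func:`sampled_shapley`.
    """
    instance = np.asarray(instance, dtype=float)
    background = np.asarray(background, dtype=float)
    m = instance.size
    if m > max_features:
        raise ValueError(
            f"{m} features exceed the exact-enumeration limit ({max_features}); "
            "use sampled_shapley instead"
        )
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D matrix")
    values = _all_coalition_values(score_fn, instance, background, m)
    n_classes = values.shape[1]
    fact = [math.factorial(i) for i in range(m + 1)]
    weights = np.array(
        [fact[s] * fact[m - s - 1] / fact[m] for s in range(m)]
    )
    contrib = np.zeros((m, n_classes))
    for s in range(1 << m):
        size = bin(s).count("1")
        for j in range(m):
            if s >> j & 1:
                continue
            contrib[j] += weights[size] * (values[s | (1 << j)] - values[s])
    return contrib


def sampled_shapley(
    score_fn,
    instance: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling Shapley estimate with standard errors.

    Each permutation walks the features in random order, crediting each
    feature with its marginal change in coalition value; the average over
    permutations is unbiased for the exact Shapley value.  Returns
    (contributions, standard_errors), each (n_features, n_classes).
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    if rng is None:
        rng = np.random.default_rng()
    instance = np.asarray(instance, dtype=float)
    background = np.asarray(background, dtype=float)
    m = instance.size
    probe = coalition_value(score_fn, instance, [], background)
    n_classes = probe.size
    samples = np.zeros((n_permutations, m, n_classes))
    for p in range(n_permutations):
        order = rng.permutation(m)
        prev = probe
        current: list = []
        for j in order:
            current.append(j)
            val = coalition_value(score_fn, instance, current, background)
            samples[p, j] = val - prev
            prev = val
    contrib = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return contrib, se


@dataclass
class ShapleyReport:
    """Attributions for a set of samples: base values plus contributions.

    ``contributions`` has shape (n_samples, n_features, n_classes); for
    every sample and class, base_value + sum over features equals the
    model output (local accuracy).
    """

    feature_names: list
    class_labels: list
    base_values: np.ndarray
    contributions: np.ndarray
    model_outputs: np.ndarray

    def local_accuracy_residuals(self) -> np.ndarray:
        recon = self.base_values[None, :] + self.contributions.sum(axis=1)
        return np.abs(recon - self.model_outputs)

    @property
    def global_importance(self) -> pd.DataFrame:
        """Mean |contribution| per feature per class, plus overall."""
        mean_abs = np.abs(self.contributions).mean(axis=0)
        df = pd.DataFrame(mean_abs, index=self.feature_names, columns=self.class_labels)
        df["overall"] = df.mean(axis=1)
        return df

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "class_labels": [str(c) for c in self.class_labels],
            "base_values": self.base_values.tolist(),
            "contributions": self.contributions.tolist(),
            "model_outputs": self.model_outputs.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ShapleyReport":
        return cls(
            feature_names=list(d["feature_names"]),
            class_labels=list(d["class_labels"]),
            base_values=np.asarray(d["base_values"], dtype=float),
            contributions=np.asarray(d["contributions"], dtype=float),
            model_outputs=np.asarray(d["model_outputs"], dtype=float),
        )


def explain_table(
    score_fn,
    X: np.ndarray,
    background: np.ndarray,
    feature_names,
    class_labels,
    max_features: int = MAX_EXACT_FEATURES,
) -> ShapleyReport:
    """Exact Shapley attributions for every row of ``X``."""
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    base = coalition_value(score_fn, X[0], [], background)
    contribs = np.stack(
        [exact_shapley(score_fn, row, background, max_features) for row in X]
    )
    outputs = np.asarray(score_fn(X))
    return ShapleyReport(
        feature_names=list(feature_names),
        class_labels=list(class_labels),
        base_values=base,
        contributions=contribs,
        model_outputs=outputs,
    )


def summarize(report: ShapleyReport) -> pd.DataFrame:
    """Global importance ranking: features sorted by overall mean |phi|."""
    df = report.global_importance
    return df.sort_values("overall", ascending=False)


def force_decomposition(report: ShapleyReport, sample_index: int, class_label) -> dict:
    """Local explanation of one sample: base value, signed pushes, f(x).

    Contributions are ordered by decreasing magnitude and split into the
    positive (pushing the score up) and negative sets; base + sum = f(x).
    """
    c = list(report.class_labels).index(class_label)
    contrib = report.contributions[sample_index, :, c]
    order = np.argsort(-np.abs(contrib))
    ordered = [(report.feature_names[j], float(contrib[j])) for j in order]
    return {
        "sample_index": int(sample_index),
        "class": str(class_label),
        "base_value": float(report.base_values[c]),
        "contributions": ordered,
        "positive": [(n, v) for n, v in ordered if v > 0],
        "negative": [(n, v) for n, v in ordered if v < 0],
        "fx": float(report.model_outputs[sample_index, c]),
    }
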