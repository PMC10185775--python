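"""Model/Results front end for the SVM-EO wrapper.

``SVMEOModel`` is constructed from a feature table (or a plain DataFrame)
and holds the study design: fold count, fitness weight phi, optimizer
constants, standardization policy and mask convention.  ``fit`` runs the
wrapper one or more times and returns an ``SVMEOResults`` carrying the
best run, all repeat runs, cross-validated metrics with across-fold
mean +/- SD, and Shapley-based explanation helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import FeatureTable, standardize
from .eo import EOConfig
from .selection import (
    EncodingLayout,
    FitnessWeights,
    SelectionResult,
    repeat_best,
    summarize_runs,
)
from .shapley import ShapleyReport, explain_table, svm_score_fn

__all__ = ["SVMEOModel", "SVMEOResults"]


class SVMEOModel:
    """Joint feature-selection / RBF-SVM classification model for grouped tables.

    Parameters
    ----------
    table : FeatureTable
        Eyes-by-features table with participant grouping and class labels.
    phi : float
        Fitness weight between CV error and subset size (default 0.98).
    eo_config : EOConfig, optional
        Optimizer constants; defaults to V=1, a1=2, a2=1, GP=0.5,
        100 iterations, 30 particles.
    k : int
        Folds for participant-grouped CV (default 5).
    standardization : {"train_only", "global"}
        Z-scoring policy inside CV (default "train_only", leakage-safe).
    mask_convention : {"discard_above", "select_above"}
        Direction of the 0.5 threshold turning particle dimensions into a
        feature mask.
    """

    def __init__(
        self,
        table: FeatureTable,
        phi: float = 0.98,
        eo_config: EOConfig | None = None,
        k: int = 5,
        standardization: str = "train_only",
        mask_convention: str = "discard_above",
    ):
        self.table = table
        self.weights = FitnessWeights(phi=phi)
        self.eo_config = eo_config if eo_config is not None else EOConfig()
        self.k = k
        self.standardization = standardization
        self.layout = EncodingLayout(
            feature_names=tuple(table.feature_names), mask_convention=mask_convention
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SVMEOModel":
        """Build from a DataFrame with eye_id / participant_id / group columns."""
        return cls(FeatureTable(df), **kwargs)

    def fit(self, n_runs: int = 1, seed: int = 0) -> "SVMEOResults":
        """Run the wrapper ``n_runs`` times (seeds seed..seed+n_runs-1)."""
        best, runs = repeat_best(
            self.table,
            layout=self.layout,
            eo_config=self.eo_config,
            weights=self.weights,
            n_runs=n_runs,
            base_seed=seed,
            k=self.k,
            standardization=self.standardization,
        )
        return SVMEOResults(model=self, best=best, runs=runs)


class SVMEOResults:
    """Fitted wrapper: best run, repeat runs, metrics and explanations."""

    def __init__(self, model: SVMEOModel, best: SelectionResult, runs):
        self.model = model
        self.best = best
        self.runs = list(runs)

    # -- estimates ---------------------------------------------------------
    @property
    def selected_features(self) -> list:
        return self.best.selected_features

    @property
    def params(self) -> dict:
        return {
            "penalty_alpha": self.best.penalty_alpha,
            "bandwidth_beta": self.best.bandwidth_beta,
        }

    @property
    def fitness(self) -> float:
        return self.best.fitness

    @property
    def cv_report(self):
        return self.best.cv_report

    def runs_table(self) -> pd.DataFrame:
        return summarize_runs(self.runs)

    # -- explanation -------------------------------------------------------
    def explain(self, max_features: int = 15) -> ShapleyReport:
        """Exact Shapley attributions of the best model's vote-fraction scores.

        The whole (standardized) table serves as both the explained set and
        the background, matching a model-agnostic kernel explainer with a
        marginal-expectation value function.
        """
        if self.best.final_model is None:
            raise RuntimeError("best run selected no features; nothing to explain")
        table_std, _ = standardize(self.model.table)
        Xsel = table_std.data[self.selected_features].to_numpy(dtype=float)
        return explain_table(
            svm_score_fn(self.best.final_model),
            Xsel,
            Xsel,
            feature_names=self.selected_features,
            class_labels=list(self.best.final_model.class_labels),
            max_features=max_features,
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text report of the selection and CV metrics."""
        b = self.best
        lines = []
        lines.append("SVM-EO feature selection results")
        lines.append("=" * 56)
        lines.append(f"Runs: {len(self.runs)}  (best run seed {b.seed})")
        lines.append(f"Candidate features: {self.model.layout.n_features}")
        lines.append(f"Selected features ({b.n_selected}): {', '.join(b.selected_features)}")
        lines.append(
            f"Penalty alpha: {b.penalty_alpha:.4f}   Bandwidth beta: {b.bandwidth_beta:.4f}"
        )
        lines.append(f"Fitness: {b.fitness:.6f}   (phi = {self.model.weights.phi})")
        lines.append("")
        lines.append("Cross-validated metrics (mean +/- SD over folds)")
        lines.append("-" * 56)
        stats = b.cv_report.mean_sd()
        for _, row in stats.iterrows():
            sd = 0.0 if np.isnan(row["sd"]) else row["sd"]
            lines.append(
                f"{row['class']:>16} {row['metric']:<12} {row['mean']:.4f} +/- {sd:.4f}"
            )
        if len(self.runs) > 1:
            rt = self.runs_table()
            lines.append("")
            lines.append(
                "Across runs: accuracy %.4f +/- %.4f, fitness %.4f +/- %.4f"
                % (
                    rt["mean_cv_accuracy"].mean(),
                    rt["mean_cv_accuracy"].std(ddof=1),
                    rt["fitness"].mean(),
                    rt["fitness"].std(ddof=1),
                )
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SVMEOResults: {self.best.n_selected} features, "
            f"fitness={self.best.fitness:.4f}>"
        )
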