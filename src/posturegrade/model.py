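"""Severity-grading model and results, statsmodels style.

:class:`PostureSeverityModel` wraps a cohort of posture feature vectors with
clinician MDS-UPDRS-III 3.13 scores. ``fit`` trains the CART grader under
one configuration and cross-validates it; ``fit_grid`` additionally selects
depth, split strategy and the feature subset by minimizing the
human-machine objective on pooled out-of-fold predictions. Both return a
:class:`PostureSeverityResults` carrying the fitted tree, out-of-fold
scores, agreement metrics (macro one-vs-rest and ICC) and a ``summary()``
table.

The default configuration is the selected optimal grader: features
F1, F2, F3, F4, F5, F7, max depth 7, 'random' splitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .metrics import (
    GradingMetrics,
    ICCResult,
    ObjectiveConfig,
    icc,
    macro_ovr_metrics,
    objective,
)
from .selection import CVConfig, GridResult, GridSpec, cross_validate, grid_search
from .tree import DecisionTree, TrainConfig, fit_tree

__all__ = ["OPTIMAL_FEATURES", "OPTIMAL_CONFIG", "PostureSeverityModel",
           "PostureSeverityResults"]

#: feature subset of the selected optimal grader
OPTIMAL_FEATURES: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F7")

#: depth / split strategy of the selected optimal grader
OPTIMAL_CONFIG = {"max_depth": 7, "splitter": "random"}


class PostureSeverityModel:
    """Posture-severity grading model over a scored cohort.

    Parameters
    ----------
    X : array-like, shape (n_subjects, n_features)
        Posture feature matrix.
    y : array-like of int
        Clinician severity scores, 0..4.
    feature_names : sequence of str
        Column names of ``X``.
    """

    def __init__(self, X, y, feature_names: Sequence[str]):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] == 0:
            raise InvalidInputError("X must be a non-empty 2-D matrix")
        if X.shape[0] != y.size:
            raise InvalidInputError("X and y length mismatch")
        if len(feature_names) != X.shape[1]:
            raise InvalidInputError("feature_names length must match X columns")
        if np.any((y < 0) | (y > 4)):
            raise InvalidInputError("scores must lie in 0..4")
        self.exog = X
        self.endog = y
        self.feature_names = tuple(feature_names)

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        features: Sequence[str] = OPTIMAL_FEATURES,
        score_col: str = "score",
    ) -> "PostureSeverityModel":
        """Build the model from a cohort table (columns F1..F8 and a score)."""
        missing = [c for c in (*features, score_col) if c not in cohort.columns]
        if missing:
            raise InvalidInputError(f"cohort table missing columns: {missing}")
        return cls(cohort[list(features)].to_numpy(), cohort[score_col].to_numpy(),
                   feature_names=features)

    # ------------------------------------------------------------------

    def fit(
        self,
        max_depth: int = OPTIMAL_CONFIG["max_depth"],
        splitter: str = OPTIMAL_CONFIG["splitter"],
        lam: float = 1.0,
        cv: CVConfig | None = None,
        seed: int = 0,
    ) -> "PostureSeverityResults":
        """Train under one configuration and evaluate by k-fold CV."""
        cfg = TrainConfig(max_depth=max_depth, splitter=splitter, seed=seed)
        cv = cv if cv is not None else CVConfig(seed=seed)
        obj = ObjectiveConfig(lam=lam)
        oof = cross_validate(self.exog, self.endog, cfg, cv)
        tree = fit_tree(self.exog, self.endog, cfg, feature_names=self.feature_names)
        return PostureSeverityResults(
            model=self,
            tree=tree,
            config=cfg,
            cv=cv,
            objective_config=obj,
            features_used=self.feature_names,
            oof_pred=oof,
        )

    def fit_grid(
        self,
        grid: GridSpec,
        lam: float = 1.0,
        cv: CVConfig | None = None,
        seed: int = 0,
    ) -> "PostureSeverityResults":
        """Grid-search depth, splitter and feature subset, then fit the winner."""
        cv = cv if cv is not None else CVConfig(seed=seed)
        obj = ObjectiveConfig(lam=lam)
        gr = grid_search(
            self.exog, self.endog, self.feature_names, grid, obj=obj, cv=cv, seed=seed
        )
        cols = [self.feature_names.index(f) for f in gr.best_subset]
        X = self.exog[:, cols]
        oof = cross_validate(X, self.endog, gr.best_config, cv)
        tree = fit_tree(X, self.endog, gr.best_config, feature_names=gr.best_subset)
        return PostureSeverityResults(
            model=self,
            tree=tree,
            config=gr.best_config,
            cv=cv,
            objective_config=obj,
            features_used=gr.best_subset,
            oof_pred=oof,
            grid_result=gr,
        )


@dataclass
class PostureSeverityResults:
    """Fitted grader with its cross-validated agreement diagnostics."""

    model: PostureSeverityModel
    tree: DecisionTree
    config: TrainConfig
    cv: CVConfig
    objective_config: ObjectiveConfig
    features_used: tuple[str, ...]
    oof_pred: np.ndarray
    grid_result: GridResult | None = None
    _metrics: GradingMetrics | None = field(default=None, repr=False)
    _icc: ICCResult | None = field(default=None, repr=False)

    # -- diagnostics ----------------------------------------------------

    @property
    def objective_value(self) -> float:
        """Human-machine objective on the pooled out-of-fold predictions."""
        return objective(self.model.endog, self.oof_pred, self.objective_config)

    @property
    def metrics(self) -> GradingMetrics:
        if self._metrics is None:
            self._metrics = macro_ovr_metrics(self.model.endog, self.oof_pred)
        return self._metrics

    @property
    def icc_machine(self) -> ICCResult:
        """ICC(2,1) between the clinician scores and the machine's
        out-of-fold scores."""
        if self._icc is None:
            self._icc = icc(self.model.endog, self.oof_pred)
        return self._icc

    def predict(self, X) -> np.ndarray:
        """Grade new subjects with the tree fitted on the full cohort."""
        return self.tree.predict(X)

    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.tree.feature_importances(), index=list(self.features_used)
        )

    # -- reporting -------------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serializable report of configuration and diagnostics."""
        rep = {
            "features": list(self.features_used),
            "config": {
                "max_depth": self.config.max_depth,
                "splitter": self.config.splitter,
                "seed": self.config.seed,
            },
            "cv": {"k": self.cv.k, "stratified": self.cv.stratified, "seed": self.cv.seed},
            "lambda": self.objective_config.lam,
            "objective": self.objective_value,
            "metrics": self.metrics.as_dict(),
            "icc_machine": self.icc_machine.as_dict(),
            "feature_importances": {
                f: float(v) for f, v in self.feature_importances().items()
            },
            "oof_predictions": [int(v) for v in self.oof_pred],
        }
        if self.grid_result is not None:
            rep["grid_report"] = self.grid_result.report
        return rep

    def summary(self) -> str:
        """Plain-text summary table."""
        m = self.metrics
        ic = self.icc_machine
        lines = [
            "Posture Severity Grading Results",
            "=" * 44,
            f"subjects:            {self.model.endog.size}",
            f"features:            {', '.join(self.features_used)}",
            f"max depth:           {self.config.max_depth}",
            f"splitter:            {self.config.splitter}",
            f"cv folds:            {self.cv.k} (stratified={self.cv.stratified})",
            f"lambda:              {self.objective_config.lam}",
            "-" * 44,
            f"objective f:         {self.objective_value:.4f}",
            f"ICC(2,1) machine:    {ic.estimate:.3f} (95% CI {ic.ci_low:.3f}-{ic.ci_high:.3f})",
            f"macro OvR accuracy:  {100 * m.accuracy:.1f}%",
            f"macro OvR sensitivity: {100 * m.sensitivity:.1f}%",
            f"macro OvR specificity: {100 * m.specificity:.1f}%",
            "-" * 44,
            "feature importances:",
        ]
        for f, v in self.feature_importances().items():
            lines.append(f"  {f}: {100 * v:.1f}%")
        return "\n".join(lines)
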