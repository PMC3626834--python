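"""Model/Results facade over the forest engine.

``MobForest`` is constructed from a DataFrame, a node-model formula and a
list of partition variables; ``fit()`` grows the ensemble and returns a
``MobForestResults`` carrying predictions, accuracy estimates, importance
scores and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .forest import (
    ForestControl,
    MobForestOutput,
    build_forest,
    get_predicted_values,
    write_predictions_csv,
)
from .mob_tree import MobControl
from .node_models import NodeModelSpec, parse_formula


class MobForest:
    """Random forest of model-based (GLM) recursive-partitioning trees.

    Parameters
    ----------
    data : DataFrame with the outcome, node-model predictors and partition
        variables (no missing values).
    formula : node-model formula ``"y ~ x1 + ... + xk"``.
    partition_variables : columns used only for splitting.
    family : "gaussian" (default), "binomial" or "poisson".
    control : ForestControl; defaults follow the standard settings
        (ntree=300, mtry=floor(p/3), subsampling fraction 0.632, alpha=1,
        minsplit=20).
    test_data : optional held-out DataFrame scored by every tree.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        formula: str,
        partition_variables: Sequence[str],
        family: str = "gaussian",
        control: ForestControl | None = None,
        test_data: pd.DataFrame | None = None,
    ):
        self.data = data
        self.spec: NodeModelSpec = parse_formula(formula, family)
        self.partition_variables = tuple(partition_variables)
        if not self.partition_variables:
            raise InputError("at least one partition variable is required")
        overlap = set(self.partition_variables) & {
            self.spec.outcome_name,
            *self.spec.predictor_names,
        }
        if overlap:
            raise InputError(
                f"partition variables overlap the node model: {sorted(overlap)}"
            )
        self.control = control if control is not None else ForestControl()
        self.test_data = test_data

    @classmethod
    def from_formula(
        cls,
        formula: str,
        data: pd.DataFrame,
        partition_variables: Sequence[str],
        **kwargs,
    ) -> "MobForest":
        return cls(data, formula, partition_variables, **kwargs)

    def fit(self) -> "MobForestResults":
        out = build_forest(
            self.data,
            self.spec,
            self.partition_variables,
            self.control,
            new_test_data=self.test_data,
        )
        return MobForestResults(self, out)


class MobForestResults:
    """Fitted forest: trees, OOB bookkeeping, accuracy and importance."""

    def __init__(self, model: MobForest, output: MobForestOutput):
        self.model = model
        self.output = output
        self.accuracy = output.accuracy
        self.importance = output.importance

    @property
    def trees(self):
        return self.output.trees

    def predicted(self, oob: bool = True, newdata: bool = False) -> pd.DataFrame:
        """Aggregated predictions: mean, SD and (continuous families) residual."""
        return get_predicted_values(self.output, use_oob=oob, use_newdata=newdata)

    def write_predictions(self, path, oob: bool = True, newdata: bool = False) -> None:
        write_predictions_csv(self.predicted(oob=oob, newdata=newdata), path)

    def plot_importance(self, path):
        from .reporting import plot_variable_importance

        return plot_variable_importance(self.importance, path)

    def plot_accuracy(self, path):
        from .reporting import plot_predictive_accuracy

        return plot_predictive_accuracy(self.accuracy, path)

    def plot_residuals(self, path):
        from .reporting import plot_residuals

        return plot_residuals(self.output, path)

    def summary(self) -> str:
        a = self.accuracy
        ctl = self.output.control
        spec = self.output.spec
        metric = a.metric_name
        lines = [
            "Model-based recursive partitioning forest",
            "=" * 57,
            f"node model:      {spec.outcome_name} ~ "
            + " + ".join(spec.predictor_names),
            f"family:          {spec.family}",
            f"partition vars:  {len(self.output.partition_variables)}",
            f"n obs:           {len(self.output.y)}",
            f"ntree:           {ctl.ntree}   mtry: "
            f"{ctl.resolve_mtry(len(self.output.partition_variables))}   "
            f"{'bootstrap' if ctl.replace else f'subsample {ctl.fraction}'}",
            f"mob controls:    alpha={ctl.mob.alpha} bonferroni={ctl.mob.bonferroni} "
            f"minsplit={ctl.mob.minsplit}",
            "-" * 57,
        ]
        per_tree = a.per_tree_oob_metric[~np.isnan(a.per_tree_oob_metric)]
        if per_tree.size:
            lines.append(
                f"per-tree OOB {metric}:  min {per_tree.min():.3f}  "
                f"median {np.median(per_tree):.3f}  max {per_tree.max():.3f}"
            )
        lines.append(f"forest OOB {metric}:    {a.forest_oob_metric:.4f}")
        lines.append(f"forest OOB MSE:   {a.forest_oob_mse:.4f}")
        if a.test_metric is not None:
            lines.append(
                f"test {metric}:          {a.test_metric:.4f}   "
                f"test MSE: {a.test_mse:.4f}"
            )
        lines.append("-" * 57)
        top = self.importance.to_frame().sort_values("rank").head(5)
        lines.append("top variables (raw permutation importance):")
        for _, row in top.iterrows():
            lines.append(f"  {row['rank']:>2}. {row['variable']:<16} {row['raw_importance']:.5f}")
        return "\n".join(lines)
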