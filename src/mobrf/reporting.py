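"""Diagnostic plots and the run report.

Every plot also emits a companion CSV of the plotted numbers so downstream
checks assert on data, never on rendered pixels.  The residual plot follows
the linear-only rule: for logistic or Poisson node models no figure is
produced and a fixed refusal message is returned instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import InputError
from .node_models import GAUSSIAN

if TYPE_CHECKING:  # pragma: no cover
    from .accuracy import AccuracyReport
    from .forest import MobForestOutput
    from .importance import ImportanceScores

RESIDUAL_PLOT_REFUSAL = (
    "Residual Plot not produced when logistic of Poisson regression is "
    "considered as the node model"
)


@dataclass
class RunReport:
    accuracy: "AccuracyReport"
    importance: "ImportanceScores"
    control_echo: dict
    artifact_paths: list[str] = field(default_factory=list)
    warnings_log: list[str] = field(default_factory=list)

    def validate_artifacts(self) -> None:
        for p in self.artifact_paths:
            path = Path(p)
            if not path.exists() or path.stat().st_size == 0:
                raise RuntimeError(f"artifact {p} missing or empty")


def _companion_csv(path: Path) -> Path:
    return path.with_suffix(".csv")


def plot_variable_importance(scores: "ImportanceScores", path) -> Path:
    """Horizontal bar chart of raw importance scores, largest on top."""
    if len(scores.variable_names) == 0:
        raise InputError("no importance scores to plot")
    path = Path(path)
    frame = scores.to_frame().sort_values("rank")
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.28 * len(frame))))
    ypos = np.arange(len(frame))[::-1]
    ax.barh(ypos, frame["raw_importance"], color="#4477aa")
    ax.set_yticks(ypos)
    ax.set_yticklabels(frame["variable"])
    ax.set_xlabel("raw permutation importance")
    ax.set_title("Variable importance")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    frame.to_csv(_companion_csv(path), index=False)
    return path


def plot_predictive_accuracy(report: "AccuracyReport", path) -> Path:
    """Histogram of per-tree OOB accuracy, the aggregated OOB estimate and —
    when test metrics exist — the aggregated test estimate."""
    path = Path(path)
    name = report.metric_name.upper() if report.metric_name == "pcc" else "pseudo R2"
    have_test = report.test_metric is not None
    npanel = 3 if have_test else 2
    fig, axes = plt.subplots(1, npanel, figsize=(4 * npanel, 3.4))
    per_tree = report.per_tree_oob_metric[~np.isnan(report.per_tree_oob_metric)]
    axes[0].hist(per_tree, bins="fd" if per_tree.size > 1 and np.ptp(per_tree) > 0 else 10,
                 color="#66ccee", edgecolor="black")
    axes[0].set_title(f"A: per-tree OOB {name}")
    axes[0].set_xlabel(name)

    def single_value_panel(ax, value, title):
        ax.bar([0], [value], width=0.4, color="#228833")
        ax.set_xticks([])
        ax.set_ylim(0, max(1.0, value * 1.1))
        ax.set_title(title)
        ax.annotate(f"{value:.3f}", (0, value), ha="center", va="bottom")

    single_value_panel(axes[1], report.forest_oob_metric, f"B: overall OOB {name}")
    if have_test:
        single_value_panel(axes[2], report.test_metric, f"C: test {name}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    report.to_frame().to_csv(_companion_csv(path), index=False)
    return path


def plot_residuals(out: "MobForestOutput", path) -> Path | str:
    """OOB residual diagnostics for the gaussian node model only.

    Returns the written path, or the refusal message (and writes nothing)
    for logistic and Poisson node models.
    """
    if out.spec.family != GAUSSIAN:
        return RESIDUAL_PLOT_REFUSAL
    from .forest import get_predicted_values

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame = get_predicted_values(out, use_oob=True)
    ok = frame["mean_prediction"].notna()
    pred = frame.loc[ok, "mean_prediction"]
    resid = frame.loc[ok, "residual"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    axes[0].scatter(pred, resid, s=12, alpha=0.6, color="#4477aa")
    axes[0].axhline(0.0, color="black", lw=0.8)
    axes[0].set_xlabel("OOB mean prediction")
    axes[0].set_ylabel("OOB residual")
    axes[0].set_title("Residuals vs predicted")
    bins = "fd" if resid.size > 1 and np.ptp(resid) > 0 else 10
    axes[1].hist(resid, bins=bins, color="#66ccee", edgecolor="black")
    axes[1].set_xlabel("OOB residual")
    axes[1].set_title("Residual histogram")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    pd.DataFrame({"mean_prediction": pred, "residual": resid}).to_csv(
        _companion_csv(path), index=False
    )
    return path
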