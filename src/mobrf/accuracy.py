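"""Predictive accuracy and error metrics on OOB, complete and test data.

Continuous node models (gaussian, poisson) are scored with a pseudo R^2 —
1 - SSE/SSTO over the evaluation cases, clamped to zero when negative — and
mean squared error.  The binomial node model is scored with the proportion
of correctly classified cases (PCC) after thresholding predicted
probabilities at ``prob_cutoff`` (ties classified as 1), plus a secondary
Brier-style MSE on the probabilities.  Forest-level metrics aggregate the
per-subject mean prediction across trees before scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedMetricError
from .node_models import BINOMIAL, NodeModelSpec

if TYPE_CHECKING:  # pragma: no cover
    from .forest import MobForestOutput


def pseudo_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Proportion of outcome variation explained, clamped to [0, 1].

    ``max(0, 1 - SSE/SSTO)`` with SSTO taken about the mean of the
    evaluation cases.  A constant ``y`` leaves SSTO = 0 and the metric
    undefined.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InputError("pseudo_r2 needs two equal-length vectors of size >= 2")
    ssto = float(np.sum((y - y.mean()) ** 2))
    if ssto == 0.0:
        raise UndefinedMetricError("pseudo R^2 undefined for a constant outcome")
    sse = float(np.sum((y - yhat) ** 2))
    return max(0.0, 1.0 - sse / ssto)


def mean_squared_error(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise InputError("mean_squared_error needs two equal-length non-empty vectors")
    return float(np.mean((y - yhat) ** 2))


def proportion_correct(y: np.ndarray, prob: np.ndarray, cutoff: float = 0.5) -> float:
    """Fraction of cases whose thresholded probability matches the 0/1 outcome.

    A probability exactly at the cutoff is classified as 1.
    """
    y = np.asarray(y, dtype=float)
    prob = np.asarray(prob, dtype=float)
    if y.shape != prob.shape or y.size < 1:
        raise InputError("proportion_correct needs two equal-length non-empty vectors")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError("outcome must be coded 0/1")
    cls = (prob >= cutoff).astype(float)
    return float(np.mean(cls == y))


def auc_wmw(y: np.ndarray, prob: np.ndarray) -> float:
    """Area under the ROC curve via the Wilcoxon-Mann-Whitney statistic.

    The fraction of (positive, negative) pairs where the positive case has
    the larger probability, counting ties as 1/2.
    """
    y = np.asarray(y, dtype=float)
    prob = np.asarray(prob, dtype=float)
    if y.shape != prob.shape:
        raise InputError("auc_wmw needs two equal-length vectors")
    pos = prob[y == 1.0]
    neg = prob[y == 0.0]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("AUC undefined when only one class is present")
    # rank-based Mann-Whitney U with midranks for ties
    combined = np.concatenate([pos, neg])
    order = np.argsort(combined, kind="stable")
    ranks = np.empty(combined.size, dtype=float)
    sorted_vals = combined[order]
    ranks[order] = np.arange(1, combined.size + 1, dtype=float)
    # midranks for ties
    i = 0
    while i < combined.size:
        j = i
        while j + 1 < combined.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class AccuracyReport:
    """Tree-level and forest-level predictive accuracy.

    ``metric`` is pseudo R^2 for gaussian/poisson node models and PCC for
    binomial.  Per-tree vectors have length ntree; entries are NaN where a
    tree has too few (or degenerate) OOB cases.
    """

    metric_name: str
    per_tree_oob_metric: np.ndarray
    per_tree_oob_mse: np.ndarray
    forest_oob_metric: float
    forest_oob_mse: float
    per_tree_all_metric: np.ndarray
    per_tree_all_mse: np.ndarray
    forest_all_metric: float
    forest_all_mse: float
    test_metric: float | None
    test_mse: float | None
    model_descriptor: dict

    def to_dict(self) -> dict:
        d = {
            "metric_name": self.metric_name,
            "per_tree_oob_metric": [None if np.isnan(v) else float(v) for v in self.per_tree_oob_metric],
            "per_tree_oob_mse": [None if np.isnan(v) else float(v) for v in self.per_tree_oob_mse],
            "forest_oob_metric": _opt(self.forest_oob_metric),
            "forest_oob_mse": _opt(self.forest_oob_mse),
            "per_tree_all_metric": [None if np.isnan(v) else float(v) for v in self.per_tree_all_metric],
            "per_tree_all_mse": [None if np.isnan(v) else float(v) for v in self.per_tree_all_mse],
            "forest_all_metric": _opt(self.forest_all_metric),
            "forest_all_mse": _opt(self.forest_all_mse),
            "test_metric": _opt(self.test_metric),
            "test_mse": _opt(self.test_mse),
            "model_descriptor": self.model_descriptor,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per tree plus forest/test summary rows."""
        ntree = len(self.per_tree_oob_metric)
        rows = [
            {
                "unit": f"tree_{k + 1}",
                f"oob_{self.metric_name}": self.per_tree_oob_metric[k],
                "oob_mse": self.per_tree_oob_mse[k],
                f"all_{self.metric_name}": self.per_tree_all_metric[k],
                "all_mse": self.per_tree_all_mse[k],
            }
            for k in range(ntree)
        ]
        rows.append(
            {
                "unit": "forest",
                f"oob_{self.metric_name}": self.forest_oob_metric,
                "oob_mse": self.forest_oob_mse,
                f"all_{self.metric_name}": self.forest_all_metric,
                "all_mse": self.forest_all_mse,
            }
        )
        if self.test_metric is not None:
            rows.append(
                {
                    "unit": "test",
                    f"oob_{self.metric_name}": self.test_metric,
                    "oob_mse": self.test_mse,
                }
            )
        return pd.DataFrame(rows)


def _opt(v):
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v


def _metric_pair(
    y: np.ndarray, pred: np.ndarray, family: str, cutoff: float
) -> tuple[float, float]:
    """(headline metric, mse) for one evaluation set; NaN when undefined."""
    if len(y) < 2:
        return np.nan, np.nan
    mse = mean_squared_error(y, pred)
    if family == BINOMIAL:
        return proportion_correct(y, pred, cutoff), mse
    try:
        return pseudo_r2(y, pred), mse
    except UndefinedMetricError:
        return np.nan, mse


def predictive_accuracy(out: "MobForestOutput", use_newdata: bool = False) -> AccuracyReport:
    """Per-tree and forest-level accuracy on OOB and complete data.

    Per-tree metrics use each tree's own OOB cases; forest metrics score the
    per-subject mean of the OOB (resp. all) predictions.  With
    ``use_newdata`` the aggregated test-set predictions are scored as well.
    """
    if use_newdata and out.predictions_test is None:
        raise InputError("no test data was supplied at build time")
    family = out.spec.family
    cutoff = out.control.prob_cutoff
    y = out.y
    ntree = out.control.ntree
    pt_oob_m = np.full(ntree, np.nan)
    pt_oob_mse = np.full(ntree, np.nan)
    pt_all_m = np.full(ntree, np.nan)
    pt_all_mse = np.full(ntree, np.nan)
    for k in range(ntree):
        oob = out.resamples[k].oob_mask
        if oob.sum() >= 2:
            pt_oob_m[k], pt_oob_mse[k] = _metric_pair(
                y[oob], out.predictions_oob[oob, k], family, cutoff
            )
        pt_all_m[k], pt_all_mse[k] = _metric_pair(
            y, out.predictions_all[:, k], family, cutoff
        )
    if np.isnan(pt_oob_m).all():
        warnings.warn("no tree has enough OOB cases; OOB metrics are undefined")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        oob_mean = np.nanmean(out.predictions_oob, axis=1)
    seen = ~np.isnan(oob_mean)
    if seen.sum() >= 2:
        f_oob_m, f_oob_mse = _metric_pair(y[seen], oob_mean[seen], family, cutoff)
    else:
        f_oob_m = f_oob_mse = np.nan
    all_mean = out.predictions_all.mean(axis=1)
    f_all_m, f_all_mse = _metric_pair(y, all_mean, family, cutoff)

    test_m = test_mse = None
    if use_newdata:
        test_mean = out.predictions_test.mean(axis=1)
        test_m, test_mse = _metric_pair(out.y_test, test_mean, family, cutoff)

    descriptor = {
        "outcome": out.spec.outcome_name,
        "predictors": list(out.spec.predictor_names),
        "family": out.spec.family,
        "partition_variables": list(out.partition_variables),
    }
    return AccuracyReport(
        metric_name="pcc" if family == BINOMIAL else "r2",
        per_tree_oob_metric=pt_oob_m,
        per_tree_oob_mse=pt_oob_mse,
        forest_oob_metric=f_oob_m,
        forest_oob_mse=f_oob_mse,
        per_tree_all_metric=pt_all_m,
        per_tree_all_mse=pt_all_mse,
        forest_all_metric=f_all_m,
        forest_all_mse=f_all_mse,
        test_metric=test_m,
        test_mse=test_mse,
        model_descriptor=descriptor,
    )
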