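"""Forest orchestration: resampling, per-tree growth, OOB bookkeeping.

Each tree is grown on a bootstrap (``replace=True``) or subsample
(``replace=False``, default fraction 0.632) of the learning data, with its
own random stream derived deterministically from ``(seed, tree index)`` so
that results are identical for any number of worker processes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .errors import InputError
from .mob_tree import MobControl, MobTree, grow_tree, is_categorical, tree_predict
from .node_models import BINOMIAL, POISSON, NodeModelSpec, canonical_family


@dataclass(frozen=True)
class ForestControl:
    """Forest growth parameters.

    ``mtry=None`` resolves to ``max(1, floor(p/3))`` at build time, with
    ``p`` the number of partition variables.  ``fraction`` is the
    without-replacement subsample fraction and is ignored when
    ``replace=True``.
    """

    ntree: int = 300
    mtry: int | None = None
    replace: bool = False
    fraction: float = 0.632
    mob: MobControl = field(default_factory=MobControl)
    prob_cutoff: float = 0.5
    seed: int = 0
    processors: int = 1

    def __post_init__(self):
        if self.ntree < 1:
            raise InputError("ntree must be a positive integer")
        if self.mtry is not None and self.mtry < 1:
            raise InputError("mtry must be a positive integer")
        if not 0.0 < self.fraction <= 1.0:
            raise InputError("fraction must lie in (0, 1]")
        if not 0.0 < self.prob_cutoff < 1.0:
            raise InputError("prob_cutoff must lie in (0, 1)")
        if self.processors < 1:
            raise InputError("processors must be a positive integer")

    def resolve_mtry(self, n_partition_variables: int) -> int:
        if self.mtry is not None:
            if self.mtry > n_partition_variables:
                raise InputError(
                    f"mtry={self.mtry} exceeds the {n_partition_variables} "
                    "partition variables"
                )
            return self.mtry
        return max(1, n_partition_variables // 3)


@dataclass(frozen=True)
class Resample:
    """In-bag multiplicities and the complementary OOB mask."""

    in_bag_counts: np.ndarray
    oob_mask: np.ndarray

    @property
    def in_bag_indices(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.in_bag_counts)), self.in_bag_counts)


def draw_resample(n: int, control: ForestControl, rng: np.random.Generator) -> Resample:
    """Uniform bootstrap (n draws with replacement) or subsample of
    ``floor(fraction * n)`` distinct cases."""
    if n < 1:
        raise InputError("n must be at least 1")
    if control.replace:
        idx = rng.integers(0, n, size=n)
        counts = np.bincount(idx, minlength=n)
    else:
        m = int(np.floor(control.fraction * n))
        if m == 0:
            raise InputError(f"fraction={control.fraction} leaves an empty in-bag sample")
        idx = rng.choice(n, size=m, replace=False)
        counts = np.zeros(n, dtype=np.int64)
        counts[idx] = 1
    return Resample(in_bag_counts=counts, oob_mask=counts == 0)


@dataclass
class MobForestOutput:
    """Everything produced by one forest run.

    ``predictions_oob`` holds NaN where a case was in-bag for that tree.
    """

    trees: list[MobTree]
    resamples: list[Resample]
    predictions_oob: np.ndarray
    predictions_all: np.ndarray
    predictions_test: np.ndarray | None
    y: np.ndarray
    y_test: np.ndarray | None
    spec: NodeModelSpec
    partition_variables: tuple[str, ...]
    control: ForestControl
    accuracy: object | None = None
    importance: object | None = None


def validate_inputs(
    data: pd.DataFrame,
    spec: NodeModelSpec,
    partition_variables: Sequence[str],
) -> None:
    """Reject missing columns, missing values and wrong outcome coding,
    naming the offending column."""
    needed = [spec.outcome_name, *spec.predictor_names, *partition_variables]
    missing_cols = [c for c in needed if c not in data.columns]
    if missing_cols:
        raise InputError(f"column(s) not found in data: {missing_cols}")
    for c in needed:
        if data[c].isna().any():
            raise InputError(f"column {c!r} contains missing values")
    for c in [spec.outcome_name, *spec.predictor_names]:
        if not pd.api.types.is_numeric_dtype(data[c]):
            raise InputError(f"model column {c!r} must be numeric")
    y = np.asarray(data[spec.outcome_name], dtype=float)
    if spec.family == BINOMIAL and not np.isin(y, (0.0, 1.0)).all():
        raise InputError(
            f"outcome column {spec.outcome_name!r} must be coded 0/1 for the "
            "binomial family"
        )
    if spec.family == POISSON and ((y < 0).any() or (y != np.floor(y)).any()):
        raise InputError(
            f"outcome column {spec.outcome_name!r} must be non-negative integers "
            "for the poisson family"
        )


def _tree_rng(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(k)]))


def _build_one_tree(
    data: pd.DataFrame,
    spec: NodeModelSpec,
    partition_variables: tuple[str, ...],
    control: ForestControl,
    mtry: int,
    new_test_data: pd.DataFrame | None,
    k: int,
):
    rng = _tree_rng(control.seed, k)
    resample = draw_resample(len(data), control, rng)
    in_bag = data.iloc[resample.in_bag_indices]
    tree = grow_tree(in_bag, spec, partition_variables, control.mob, mtry, rng)
    pred_all = tree_predict(tree, data)
    pred_test = tree_predict(tree, new_test_data) if new_test_data is not None else None
    return resample, tree, pred_all, pred_test


def build_forest(
    data: pd.DataFrame,
    spec: NodeModelSpec,
    partition_variables: Sequence[str],
    control: ForestControl | None = None,
    new_test_data: pd.DataFrame | None = None,
) -> MobForestOutput:
    """Grow the full ensemble and compute accuracy and importance.

    Per-tree streams are derived from ``(control.seed, k)``; the output is
    bit-identical for every value of ``control.processors``.
    """
    from .accuracy import predictive_accuracy
    from .importance import variable_importance

    if control is None:
        control = ForestControl()
    partition_variables = tuple(partition_variables)
    validate_inputs(data, spec, partition_variables)
    if new_test_data is not None:
        validate_inputs(new_test_data, spec, partition_variables)
    data = data.reset_index(drop=True)
    if new_test_data is not None:
        new_test_data = new_test_data.reset_index(drop=True)
    mtry = control.resolve_mtry(len(partition_variables))
    n = len(data)

    def job(k):
        try:
            return _build_one_tree(
                data, spec, partition_variables, control, mtry, new_test_data, k
            )
        except Exception as exc:
            raise RuntimeError(
                f"tree {k + 1} (seed {control.seed}, stream {k}) failed: {exc}"
            ) from exc

    if control.processors == 1:
        results = [job(k) for k in range(control.ntree)]
    else:
        results = Parallel(n_jobs=control.processors, backend="loky")(
            delayed(job)(k) for k in range(control.ntree)
        )

    trees, resamples = [], []
    predictions_all = np.empty((n, control.ntree))
    predictions_oob = np.full((n, control.ntree), np.nan)
    predictions_test = (
        np.empty((len(new_test_data), control.ntree)) if new_test_data is not None else None
    )
    for k, (resample, tree, pred_all, pred_test) in enumerate(results):
        resamples.append(resample)
        trees.append(tree)
        predictions_all[:, k] = pred_all
        predictions_oob[resample.oob_mask, k] = pred_all[resample.oob_mask]
        if predictions_test is not None:
            predictions_test[:, k] = pred_test

    out = MobForestOutput(
        trees=trees,
        resamples=resamples,
        predictions_oob=predictions_oob,
        predictions_all=predictions_all,
        predictions_test=predictions_test,
        y=np.asarray(data[spec.outcome_name], dtype=float),
        y_test=(
            np.asarray(new_test_data[spec.outcome_name], dtype=float)
            if new_test_data is not None
            else None
        ),
        spec=spec,
        partition_variables=partition_variables,
        control=control,
    )
    out.accuracy = predictive_accuracy(out, use_newdata=new_test_data is not None)
    out.importance = variable_importance(out, data)
    return out


def get_predicted_values(
    out: MobForestOutput, use_oob: bool = True, use_newdata: bool = False
) -> pd.DataFrame:
    """Per-subject aggregate predictions across trees.

    Columns: ``mean_prediction`` (mean of the present per-tree predictions),
    ``sd_prediction`` (their sample standard deviation; 0 for a single
    prediction) and — for gaussian and poisson node models only —
    ``residual`` (observed minus mean prediction).  With ``use_newdata`` the
    OOB flag is ignored and the test-set predictions are aggregated.
    Subjects that were never OOB get NaN in every column.
    """
    if use_newdata:
        if out.predictions_test is None:
            raise InputError("no test data was supplied at build time")
        mat, y = out.predictions_test, out.y_test
    elif use_oob:
        mat, y = out.predictions_oob, out.y
    else:
        mat, y = out.predictions_all, out.y

    n_present = np.sum(~np.isnan(mat), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=1)
        sd = np.nanstd(mat, axis=1, ddof=1)
    sd[n_present == 1] = 0.0
    never = n_present == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} subject(s) were never out-of-bag; their "
            "aggregates are reported as missing"
        )
        mean[never] = np.nan
        sd[never] = np.nan
    frame = pd.DataFrame({"mean_prediction": mean, "sd_prediction": sd})
    if out.spec.family == BINOMIAL:
        frame.attrs["residuals"] = (
            "residuals are reported only when linear or Poisson regression is "
            "considered"
        )
    else:
        frame["residual"] = y - mean
    return frame


def write_predictions_csv(frame: pd.DataFrame, path) -> None:
    """CSV with columns [id, mean_prediction, sd_prediction, residual]."""
    outframe = frame.copy()
    if "residual" not in outframe.columns:
        outframe["residual"] = np.nan
    outframe.insert(0, "id", np.arange(1, len(outframe) + 1))
    outframe.to_csv(path, index=False)
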