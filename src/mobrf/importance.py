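"""Permutation accuracy importance.

For every tree and partition variable, the variable's values are permuted
among that tree's OOB cases and the tree's OOB accuracy is recomputed; the
degradation (MSE_permuted - MSE for continuous outcomes, PCC - PCC_permuted
for binary) averaged over trees is the raw importance score.  Larger always
means more important.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import InputError
from .mob_tree import tree_predict
from .node_models import BINOMIAL

if TYPE_CHECKING:  # pragma: no cover
    from .forest import MobForestOutput


@dataclass
class ImportanceScores:
    variable_names: tuple[str, ...]
    raw_scores: np.ndarray
    n_trees_contributing: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table [variable, raw_importance, rank] (rank 1 = largest)."""
        order = np.argsort(-self.raw_scores, kind="stable")
        rank = np.empty(len(order), dtype=int)
        rank[order] = np.arange(1, len(order) + 1)
        return pd.DataFrame(
            {
                "variable": list(self.variable_names),
                "raw_importance": self.raw_scores,
                "rank": rank,
            }
        )


def permute_oob_column(
    data: pd.DataFrame,
    variable: str,
    oob_mask: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Copy of ``data`` with the variable's OOB values uniformly permuted.

    In-bag rows and all other columns are untouched.  Fewer than two OOB
    cases cannot be permuted; the copy is returned unchanged with a warning.
    """
    if variable not in data.columns:
        raise InputError(f"variable {variable!r} not in data")
    oob_mask = np.asarray(oob_mask, dtype=bool)
    out = data.copy()
    idx = np.nonzero(oob_mask)[0]
    if idx.size < 2:
        warnings.warn(
            f"fewer than 2 OOB cases; {variable!r} left unpermuted", stacklevel=2
        )
        return out
    perm = rng.permutation(idx.size)
    col = out.columns.get_loc(variable)
    out.iloc[idx, col] = out.iloc[idx[perm], col].to_numpy()
    return out


def _variable_stream(seed: int, tree_index: int, variable: str) -> np.random.Generator:
    # keyed by the variable NAME so reordering the partition list cannot
    # change any variable's permutations
    crc = zlib.crc32(variable.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), 1_000_003, int(tree_index), crc])
    )


def variable_importance(
    out: "MobForestOutput", data: pd.DataFrame, rng: np.random.Generator | None = None
) -> ImportanceScores:
    """Raw permutation importance of every partition variable.

    One permutation per (tree, variable) pair, each from its own stream
    derived from the forest seed, the tree index and the variable name.
    Passing ``rng`` overrides the seed component (a single integer is drawn
    from it to reseed the scheme).
    """
    from .accuracy import mean_squared_error, proportion_correct

    seed = int(out.control.seed)
    if rng is not None:
        seed = int(rng.integers(0, 2**31 - 1))
    data = data.reset_index(drop=True)
    variables = out.partition_variables
    binary = out.spec.family == BINOMIAL
    cutoff = out.control.prob_cutoff
    p = len(variables)
    contrib = np.zeros((out.control.ntree, p))
    contributing = np.zeros(p, dtype=int)

    for k, (tree, resample) in enumerate(zip(out.trees, out.resamples)):
        oob = resample.oob_mask
        if oob.sum() < 2:
            continue
        y_oob = out.y[oob]
        base_pred = out.predictions_all[oob, k]
        if binary:
            base = proportion_correct(y_oob, base_pred, cutoff)
        else:
            base = mean_squared_error(y_oob, base_pred)
        oob_rows = data[oob]
        used = tree.partition_variables_used
        for j, v in enumerate(variables):
            contributing[j] += 1
            if v not in used and v not in out.spec.predictor_names:
                continue  # predictions cannot change; contribution is 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                permuted = permute_oob_column(
                    oob_rows, v, np.ones(len(oob_rows), dtype=bool),
                    _variable_stream(seed, k, v),
                )
            perm_pred = tree_predict(tree, permuted)
            if binary:
                contrib[k, j] = base - proportion_correct(y_oob, perm_pred, cutoff)
            else:
                contrib[k, j] = mean_squared_error(y_oob, perm_pred) - base
    raw = contrib.mean(axis=0)
    return ImportanceScores(
        variable_names=tuple(variables),
        raw_scores=raw,
        n_trees_contributing=contributing,
    )
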