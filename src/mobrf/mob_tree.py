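"""Single model-based recursive partitioning (MOB) trees.

Each node fits the parametric node model, tests the stability of its
coefficients along every candidate partition variable via score-fluctuation
statistics, splits on the most unstable variable at the objective-optimal
cutpoint, and recurses.  The forest ingredient is that only a random subset
of ``mtry`` partition variables is tested at every node.

Fluctuation statistics
----------------------
Let ``s_i`` be the estimating-function contribution of observation *i*
(an ``n x k`` matrix with zero column sums) and ``J = sum_i s_i s_i'``.

* ordered variable ``z``: order the scores by ``z``, form the decorrelated
  cumulative-sum process ``W(t) = J^{-1/2} C_{nt}`` with ``C_m`` the partial
  sum of the first ``m`` scores, and take the supremum over candidate
  breakpoints in the trimmed range of ``||W(t)||^2 / (t(1-t))`` (supLM).
  Its null distribution is the supremum of a squared tied-down Bessel
  process, approximated here by a cached Monte-Carlo table.
* categorical ``z`` with L levels: ``sum_l (n/n_l) S_l' J^{-1} S_l`` where
  ``S_l`` is the score sum within level *l*; asymptotically chi-square with
  ``(L-1) k`` degrees of freedom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, SingularFitError
from .node_models import (
    GAUSSIAN,
    FittedNodeModel,
    NodeModelSpec,
    design_matrix,
    estimating_functions,
    fit_irls,
    fit_node_model,
    log_likelihood,
    predict_response,
)


@dataclass(frozen=True)
class MobControl:
    """Growth parameters of a single MOB tree.

    alpha: a node is split only if some tested variable's (possibly
    Bonferroni-adjusted) instability p-value falls below it (default 1,
    i.e. grow until the sample-size rules stop).  minsplit is the minimum
    number of observations in any node.  trim is the fraction of the
    ordering excluded at each end when maximizing the supLM statistic.
    """

    alpha: float = 1.0
    bonferroni: bool = False
    minsplit: int = 20
    trim: float = 0.1
    max_categorical_levels: int = 10

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise InputError("alpha must lie in (0, 1]")
        if self.minsplit < 1:
            raise InputError("minsplit must be a positive integer")
        if not 0.0 < self.trim < 0.5:
            raise InputError("trim must lie in (0, 0.5)")
        if self.max_categorical_levels < 2:
            raise InputError("max_categorical_levels must be at least 2")


@dataclass(frozen=True)
class InstabilityResult:
    variable: str
    statistic: float
    p_value: float


@dataclass(frozen=True)
class SplitRule:
    """Binary routing rule: ordered values <= threshold go left, categorical
    levels in left_levels go left."""

    variable: str
    kind: str  # "ordered_threshold" | "categorical_partition"
    threshold: float | None = None
    left_levels: frozenset | None = None

    def __post_init__(self):
        if self.kind == "ordered_threshold":
            if self.threshold is None:
                raise InputError("ordered split needs a threshold")
        elif self.kind == "categorical_partition":
            if not self.left_levels:
                raise InputError("categorical split needs left levels")
            object.__setattr__(self, "left_levels", frozenset(self.left_levels))
        else:
            raise InputError(f"unknown split kind {self.kind!r}")

    def goes_left(self, values: pd.Series) -> np.ndarray:
        if self.kind == "ordered_threshold":
            return np.asarray(values, dtype=float) <= self.threshold
        return values.isin(self.left_levels).to_numpy()


@dataclass
class TreeNode:
    node_id: int
    model: FittedNodeModel
    n_fit: int
    split: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_terminal(self) -> bool:
        return self.split is None


@dataclass
class MobTree:
    """Binary MOB tree: internal nodes carry a SplitRule, every node stores
    the model fitted on its training rows (terminal-node models make the
    predictions)."""

    root: TreeNode
    spec: NodeModelSpec
    partition_variables: tuple[str, ...]
    known_levels: dict[str, tuple] = field(default_factory=dict)

    @property
    def partition_variables_used(self) -> set[str]:
        used: set[str] = set()

        def walk(node: TreeNode):
            if node.split is not None:
                used.add(node.split.variable)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return used

    @property
    def n_terminal_nodes(self) -> int:
        def count(node: TreeNode) -> int:
            if node.is_terminal:
                return 1
            return count(node.left) + count(node.right)

        return count(self.root)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def encode(node: TreeNode) -> dict:
            d = {
                "node_id": node.node_id,
                "n_fit": node.n_fit,
                "coefficients": [float(c) for c in node.model.coefficients],
                "converged": bool(node.model.converged),
            }
            if node.split is not None:
                rule = {"variable": node.split.variable, "kind": node.split.kind}
                if node.split.kind == "ordered_threshold":
                    rule["threshold"] = float(node.split.threshold)
                else:
                    rule["left_levels"] = sorted(map(str, node.split.left_levels))
                d["split"] = rule
                d["left"] = encode(node.left)
                d["right"] = encode(node.right)
            return d

        return {
            "outcome": self.spec.outcome_name,
            "predictors": list(self.spec.predictor_names),
            "family": self.spec.family,
            "partition_variables": list(self.partition_variables),
            "known_levels": {k: [str(v) for v in vs] for k, vs in self.known_levels.items()},
            "root": encode(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MobTree":
        spec = NodeModelSpec(d["outcome"], tuple(d["predictors"]), d["family"])

        def decode(nd: dict) -> TreeNode:
            model = FittedNodeModel(
                spec,
                np.asarray(nd["coefficients"], dtype=float),
                n_fit=int(nd["n_fit"]),
                converged=bool(nd["converged"]),
            )
            node = TreeNode(int(nd["node_id"]), model, int(nd["n_fit"]))
            if "split" in nd:
                r = nd["split"]
                if r["kind"] == "ordered_threshold":
                    node.split = SplitRule(r["variable"], r["kind"], threshold=float(r["threshold"]))
                else:
                    node.split = SplitRule(
                        r["variable"], r["kind"], left_levels=frozenset(r["left_levels"])
                    )
                node.left = decode(nd["left"])
                node.right = decode(nd["right"])
            return node

        return cls(
            root=decode(d["root"]),
            spec=spec,
            partition_variables=tuple(d["partition_variables"]),
            known_levels={k: tuple(vs) for k, vs in d.get("known_levels", {}).items()},
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "MobTree":
        return cls.from_dict(json.loads(s))

    def to_text(self) -> str:
        """Human-readable indented rendering of the tree."""
        lines: list[str] = []
        names = self.spec.coefficient_names

        def fmt_model(node: TreeNode) -> str:
            coefs = ", ".join(f"{nm}={c:.4g}" for nm, c in zip(names, node.model.coefficients))
            return f"n={node.n_fit}: {coefs}"

        def walk(node: TreeNode, depth: int, label: str):
            pad = "  " * depth
            if node.is_terminal:
                lines.append(f"{pad}[{node.node_id}] {label}* {fmt_model(node)}")
            else:
                s = node.split
                if s.kind == "ordered_threshold":
                    desc = f"{s.variable} <= {s.threshold:.6g}"
                else:
                    desc = f"{s.variable} in {{{', '.join(sorted(map(str, s.left_levels)))}}}"
                lines.append(f"{pad}[{node.node_id}] {label}split: {desc} ({fmt_model(node)})")
                walk(node.left, depth + 1, "yes: ")
                walk(node.right, depth + 1, "no:  ")

        walk(self.root, 0, "")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Fluctuation (parameter-instability) tests
# ---------------------------------------------------------------------------

_SUPLM_TABLE_CACHE: dict[tuple[int, float], np.ndarray] = {}
_SUPLM_TABLE_REPS = 20000
_SUPLM_TABLE_GRID = 1000
_SUPLM_TABLE_SEED = 20130411  # fixed internal seed; not user randomness


def _suplm_null_table(k: int, trim: float) -> np.ndarray:
    """Sorted Monte-Carlo sample of sup_{t in [trim,1-trim]} ||B(t)||^2/(t(1-t))
    for a k-dimensional Brownian bridge B."""
    key = (k, round(trim, 6))
    table = _SUPLM_TABLE_CACHE.get(key)
    if table is not None:
        return table
    rng = np.random.default_rng([_SUPLM_TABLE_SEED, k, int(trim * 1e6)])
    T = _SUPLM_TABLE_GRID
    t = np.arange(1, T) / T
    sel = (t >= trim) & (t <= 1.0 - trim)
    tt = t[sel] * (1.0 - t[sel])
    sups = np.empty(_SUPLM_TABLE_REPS)
    chunk = max(1, int(2e7 // (T * k)))
    done = 0
    while done < _SUPLM_TABLE_REPS:
        m = min(chunk, _SUPLM_TABLE_REPS - done)
        steps = rng.standard_normal((m, T, k)) / np.sqrt(T)
        w = np.cumsum(steps, axis=1)
        bridge = w[:, :-1, :] - t[None, :, None] * w[:, -1:, :]
        proc = np.sum(bridge[:, sel, :] ** 2, axis=2) / tt[None, :]
        sups[done : done + m] = proc.max(axis=1)
        done += m
    table = np.sort(sups)
    _SUPLM_TABLE_CACHE[key] = table
    return table


def _suplm_pvalue(stat: float, k: int, trim: float) -> float:
    # floored at the Monte-Carlo resolution: the table cannot resolve
    # smaller tail probabilities, and p-values must stay strictly positive
    table = _suplm_null_table(k, trim)
    idx = np.searchsorted(table, stat, side="left")
    return float(max((len(table) - idx) / len(table), 1.0 / (len(table) + 1)))


def _decorrelating_inverse(scores: np.ndarray) -> np.ndarray | None:
    """Pseudo-inverse of J = sum_i s_i s_i'; None when the scores are all ~0."""
    J = scores.T @ scores
    scale = np.trace(J)
    if not np.isfinite(scale) or scale <= 1e-12 * max(1, scores.shape[0]):
        return None
    return np.linalg.pinv(J, hermitian=True)


def is_categorical(z: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(z) or isinstance(
        z.dtype, pd.CategoricalDtype
    )


def test_parameter_instability(
    scores: np.ndarray,
    z: pd.Series,
    control: MobControl,
    variable: str = "z",
) -> InstabilityResult:
    """Score-fluctuation test of coefficient stability along ``z``.

    Ordered ``z`` yields the supLM statistic maximized over breakpoints
    between distinct values inside the trimmed range; categorical ``z``
    yields the level-sum chi-square.  A constant ``z`` (or a degenerate
    score matrix) cannot exhibit fluctuation and returns p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    z = pd.Series(np.asarray(z), copy=False)
    if len(z) != n:
        raise InputError("scores and z must have the same length")

    if z.nunique(dropna=False) <= 1:
        return InstabilityResult(variable, 0.0, 1.0)
    Jinv = _decorrelating_inverse(scores)
    if Jinv is None:
        return InstabilityResult(variable, 0.0, 1.0)

    if is_categorical(z):
        codes, levels = pd.factorize(z, sort=True)
        L = len(levels)
        if L > control.max_categorical_levels:
            raise InputError(
                f"variable {variable!r} has {L} levels, exceeding the limit of "
                f"{control.max_categorical_levels}"
            )
        stat = 0.0
        for l in range(L):
            sel = codes == l
            n_l = int(sel.sum())
            S_l = scores[sel].sum(axis=0)
            stat += (n / n_l) * float(S_l @ Jinv @ S_l)
        df = (L - 1) * k
        # strictly positive floor keeps the alpha -> 0 stopping guarantee
        p = max(float(stats.chi2.sf(stat, df)), 1e-300)
        return InstabilityResult(variable, float(stat), p)

    order = np.argsort(np.asarray(z, dtype=float), kind="stable")
    zs = np.asarray(z, dtype=float)[order]
    C = np.cumsum(scores[order], axis=0)
    # breakpoints only between distinct consecutive values, inside the trim
    boundary = np.nonzero(zs[:-1] < zs[1:])[0] + 1  # left-block sizes
    lo = int(np.ceil(n * control.trim))
    hi = int(np.floor(n * (1.0 - control.trim)))
    cand = boundary[(boundary >= lo) & (boundary <= hi)]
    if cand.size == 0:
        return InstabilityResult(variable, 0.0, 1.0)
    Ci = C[cand - 1]
    t = cand / n
    quad = np.einsum("ij,jk,ik->i", Ci, Jinv, Ci)
    proc = quad / (t * (1.0 - t))
    stat = float(proc.max())
    p = _suplm_pvalue(stat, k, control.trim)
    return InstabilityResult(variable, stat, p)


# the leading "test_" is domain vocabulary, not a pytest test
test_parameter_instability.__test__ = False  # type: ignore[attr-defined]


def select_split_variable(
    results: Sequence[InstabilityResult], control: MobControl
) -> str | None:
    """Most unstable variable, or None if nothing clears alpha.

    With Bonferroni enabled every p-value is multiplied by the number of
    variables tested in this node (capped at 1).  Ties go to the earliest
    variable in the tested order.
    """
    if not results:
        raise InputError("no instability results supplied")
    m = len(results)
    best_name, best_p = None, np.inf
    for r in results:
        p = min(1.0, r.p_value * m) if control.bonferroni else r.p_value
        if p < best_p - 1e-15:
            best_name, best_p = r.variable, p
    if best_name is not None and best_p < control.alpha:
        return best_name
    return None


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------


def _gaussian_child_sse(
    X: np.ndarray, y: np.ndarray, order: np.ndarray, cut_sizes: np.ndarray
) -> np.ndarray | None:
    """Pooled SSE for every candidate left-block size (gaussian fast path).

    Uses prefix sums of X'X and X'y along the ordering; candidates whose
    child normal equations are singular get +inf.
    """
    Xo, yo = X[order], y[order]
    k = X.shape[1]
    outer = np.einsum("ij,ik->ijk", Xo, Xo)
    cXX = np.cumsum(outer, axis=0)
    cXy = np.cumsum(Xo * yo[:, None], axis=0)
    cyy = np.cumsum(yo * yo)
    XX_tot, Xy_tot, yy_tot = cXX[-1], cXy[-1], cyy[-1]
    sse = np.full(cut_sizes.shape, np.inf)
    for i, m in enumerate(cut_sizes):
        XXl, Xyl, yyl = cXX[m - 1], cXy[m - 1], cyy[m - 1]
        XXr, Xyr, yyr = XX_tot - XXl, Xy_tot - Xyl, yy_tot - yyl
        try:
            cl = np.linalg.cholesky(XXl)
            cr = np.linalg.cholesky(XXr)
        except np.linalg.LinAlgError:
            continue
        bl = np.linalg.solve(cl.T, np.linalg.solve(cl, Xyl))
        br = np.linalg.solve(cr.T, np.linalg.solve(cr, Xyr))
        sse[i] = (yyl - bl @ Xyl) + (yyr - br @ Xyr)
    return sse


def _glm_objective(
    spec: NodeModelSpec, rows: pd.DataFrame, start: np.ndarray | None
) -> tuple[float, np.ndarray] | None:
    try:
        m = fit_node_model(spec, rows, start=start)
    except SingularFitError:
        return None
    return log_likelihood(m, rows), m.coefficients


def search_split(
    rows: pd.DataFrame,
    variable: str,
    spec: NodeModelSpec,
    control: MobControl,
) -> SplitRule | None:
    """Exhaustive objective scan for the best admissible binary split.

    Ordered variables: all midpoints between consecutive distinct values.
    Categoricals: all 2^(L-1)-1 binary level partitions.  The objective is
    the summed maximized log-likelihood of the two child fits (pooled SSE
    for gaussian); both children must have at least ``minsplit`` rows and a
    non-singular fit.  Returns None if no candidate is admissible.
    """
    if variable not in rows.columns:
        raise InputError(f"partition variable {variable!r} not in data")
    z = rows[variable]
    n = len(rows)
    minsplit = control.minsplit

    if is_categorical(z):
        codes, levels = pd.factorize(z, sort=True)
        L = len(levels)
        if L < 2:
            return None
        best_obj, best_rule = -np.inf, None
        level_idx = list(range(L))
        # enumerate partitions with level 0 pinned to the left side
        for r in range(0, L - 1):
            for rest in combinations(level_idx[1:], r):
                left = (0,) + rest
                mask = np.isin(codes, left)
                nl = int(mask.sum())
                if nl < minsplit or n - nl < minsplit:
                    continue
                ol = _glm_objective(spec, rows[mask], None)
                orr = _glm_objective(spec, rows[~mask], None)
                if ol is None or orr is None:
                    continue
                obj = ol[0] + orr[0]
                if obj > best_obj + 1e-12:
                    best_obj = obj
                    best_rule = SplitRule(
                        variable,
                        "categorical_partition",
                        left_levels=frozenset(levels[list(left)]),
                    )
        return best_rule

    zv = np.asarray(z, dtype=float)
    order = np.argsort(zv, kind="stable")
    zs = zv[order]
    boundary = np.nonzero(zs[:-1] < zs[1:])[0] + 1
    cand = boundary[(boundary >= minsplit) & (boundary <= n - minsplit)]
    if cand.size == 0:
        return None

    if spec.family == GAUSSIAN:
        X = design_matrix(spec, rows)
        y = np.asarray(rows[spec.outcome_name], dtype=float)
        sse = _gaussian_child_sse(X, y, order, cand)
        if not np.isfinite(sse).any():
            return None
        best = int(np.argmin(sse))  # first minimum -> smallest threshold
        m = cand[best]
        return SplitRule(
            variable, "ordered_threshold", threshold=float((zs[m - 1] + zs[m]) / 2.0)
        )

    rows_sorted = rows.iloc[order]
    best_obj, best_m = -np.inf, None
    warm_left = warm_right = None
    for m in cand:
        left = rows_sorted.iloc[:m]
        right = rows_sorted.iloc[m:]
        ol = _glm_objective(spec, left, warm_left)
        orr = _glm_objective(spec, right, warm_right)
        if ol is None or orr is None:
            continue
        warm_left, warm_right = ol[1], orr[1]
        obj = ol[0] + orr[0]
        if obj > best_obj + 1e-12:
            best_obj, best_m = obj, m
    if best_m is None:
        return None
    return SplitRule(
        variable,
        "ordered_threshold",
        threshold=float((zs[best_m - 1] + zs[best_m]) / 2.0),
    )


# ---------------------------------------------------------------------------
# Tree growth and prediction
# ---------------------------------------------------------------------------


def grow_tree(
    rows: pd.DataFrame,
    spec: NodeModelSpec,
    partition_variables: Sequence[str],
    control: MobControl,
    mtry: int,
    rng: np.random.Generator,
) -> MobTree:
    """Grow one MOB tree with random candidate subsets of size ``mtry``.

    At every node a fresh uniform subset of ``mtry`` partition variables is
    drawn (without replacement) and tested for parameter instability; the
    node splits on the selected variable at the optimal cutpoint and recurses
    while nodes stay admissible (``n >= 2*minsplit`` and p-values clear
    alpha).
    """
    partition_variables = list(partition_variables)
    p = len(partition_variables)
    if not partition_variables:
        raise InputError("at least one partition variable is required")
    if not 1 <= mtry <= p:
        raise InputError(f"mtry must lie in [1, {p}], got {mtry}")
    missing = [v for v in partition_variables if v not in rows.columns]
    if missing:
        raise InputError(f"partition variable(s) missing from data: {missing}")

    known_levels = {
        v: tuple(pd.factorize(rows[v], sort=True)[1])
        for v in partition_variables
        if is_categorical(rows[v])
    }
    counter = [0]

    def build(node_rows: pd.DataFrame) -> TreeNode:
        counter[0] += 1
        node_id = counter[0]
        model = fit_node_model(spec, node_rows)
        node = TreeNode(node_id, model, n_fit=len(node_rows))
        if len(node_rows) < 2 * control.minsplit or not model.converged:
            return node
        subset_idx = np.sort(rng.choice(p, size=mtry, replace=False))
        scores = estimating_functions(model, node_rows)
        results = []
        for j in subset_idx:
            v = partition_variables[j]
            results.append(
                test_parameter_instability(scores, node_rows[v], control, variable=v)
            )
        chosen = select_split_variable(results, control)
        if chosen is None:
            return node
        rule = search_split(node_rows, chosen, spec, control)
        if rule is None:
            return node
        mask = rule.goes_left(node_rows[chosen])
        node.split = rule
        node.left = build(node_rows[mask])
        node.right = build(node_rows[~mask])
        return node

    root = build(rows)
    return MobTree(
        root=root,
        spec=spec,
        partition_variables=tuple(partition_variables),
        known_levels=known_levels,
    )


def tree_predict(tree: MobTree, rows: pd.DataFrame) -> np.ndarray:
    """Route every row to its terminal node and evaluate that node's model.

    Categorical levels unseen during training are routed left with a warning.
    """
    out = np.empty(len(rows), dtype=float)
    if len(rows) == 0:
        return out

    def route(node: TreeNode, idx: np.ndarray, sub: pd.DataFrame):
        if node.is_terminal:
            out[idx] = predict_response(node.model, sub)
            return
        rule = node.split
        values = sub[rule.variable]
        if rule.kind == "categorical_partition":
            known = tree.known_levels.get(rule.variable)
            if known is not None:
                unseen = ~values.isin(known)
                if unseen.any():
                    warnings.warn(
                        f"{int(unseen.sum())} unseen level(s) of "
                        f"{rule.variable!r} routed left",
                        stacklevel=2,
                    )
                    # unseen levels go left: add them to the left mask below
            mask = values.isin(rule.left_levels).to_numpy()
            if known is not None:
                mask = mask | (~values.isin(known)).to_numpy()
        else:
            mask = np.asarray(values, dtype=float) <= rule.threshold
        route(node.left, idx[mask], sub[mask])
        route(node.right, idx[~mask], sub[~mask])

    route(tree.root, np.arange(len(rows)), rows)
    return out
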