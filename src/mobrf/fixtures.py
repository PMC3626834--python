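"""Synthetic datasets with known piecewise-model subgroup structure.

These generators produce exactly the data-generating process model-based
recursive partitioning assumes: the covariate space is partitioned into
subgroups by a few informative partition variables, and within each subgroup
the outcome follows the node model with subgroup-specific coefficients.
A :class:`TruthRecord` side-car records the generative truth so recovery
tests can score split-variable selection and importance rankings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .node_models import BINOMIAL, GAUSSIAN, POISSON, canonical_family


@dataclass(frozen=True)
class PredictorSpec:
    """A node-model predictor: standard-normal / uniform numeric draw, or a
    0/1 treatment dummy derived from a uniform group assignment."""

    name: str
    kind: str = "normal"  # "normal" | "uniform" | values via loc/scale
    loc: float = 0.0
    scale: float = 1.0


@dataclass(frozen=True)
class PartitionVariableSpec:
    name: str
    kind: str = "numeric"  # "numeric" | "categorical"
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "categorical" and len(self.levels) < 2:
            raise InputError(f"categorical variable {self.name!r} needs >= 2 levels")


@dataclass(frozen=True)
class SubgroupRule:
    """A subgroup: membership predicate over the partition variables plus the
    node-model coefficient vector that holds inside it."""

    label: str
    predicate: Callable[[pd.DataFrame], np.ndarray]
    coefficients: tuple[float, ...]


@dataclass(frozen=True)
class SubgroupDataSpec:
    n: int
    family: str
    predictors: tuple[PredictorSpec, ...]
    n_treatment_groups: int  # 0 = no treatment dummies; J groups -> J-1 dummies
    partition_variables: tuple[PartitionVariableSpec, ...]
    subgroup_rules: tuple[SubgroupRule, ...]
    informative_variables: tuple[str, ...]
    noise_sd: float = 1.0
    seed: int = 0
    correlation: np.ndarray | None = None  # Gaussian copula over numeric z's

    def __post_init__(self):
        object.__setattr__(self, "family", canonical_family(self.family))
        if self.n < 1:
            raise InputError("n must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        unknown = set(self.informative_variables) - {
            v.name for v in self.partition_variables
        }
        if unknown:
            raise InputError(f"informative variables not declared: {sorted(unknown)}")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        names = [p.name for p in self.predictors]
        names += [f"T{j}" for j in range(2, self.n_treatment_groups + 1)]
        return tuple(names)

    @property
    def n_coefficients(self) -> int:
        return 1 + len(self.predictor_names)


@dataclass
class TruthRecord:
    subgroup_labels: np.ndarray
    coefficients: dict[str, tuple[float, ...]]
    informative_variables: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "subgroup_labels": [str(s) for s in self.subgroup_labels],
                "coefficients": {k: list(v) for k, v in self.coefficients.items()},
                "informative_variables": list(self.informative_variables),
            }
        )


def _draw_partition_variables(
    spec: SubgroupDataSpec, rng: np.random.Generator
) -> pd.DataFrame:
    numeric = [v for v in spec.partition_variables if v.kind == "numeric"]
    cols: dict[str, np.ndarray | pd.Series] = {}
    if numeric:
        q = len(numeric)
        if spec.correlation is not None:
            corr = np.asarray(spec.correlation, dtype=float)
            if corr.shape != (q, q):
                raise InputError(
                    f"correlation matrix must be {q}x{q} for the numeric variables"
                )
            chol = np.linalg.cholesky(corr)
            draws = rng.standard_normal((spec.n, q)) @ chol.T
        else:
            draws = rng.standard_normal((spec.n, q))
        for i, v in enumerate(numeric):
            cols[v.name] = draws[:, i]
    for v in spec.partition_variables:
        if v.kind == "categorical":
            cols[v.name] = pd.Series(
                rng.choice(list(v.levels), size=spec.n), dtype="object"
            )
    # preserve declared order
    return pd.DataFrame({v.name: cols[v.name] for v in spec.partition_variables})


def generate_subgroup_data(spec: SubgroupDataSpec) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a dataset from the piecewise node-model process.

    Every row must satisfy exactly one subgroup predicate; its linear
    predictor uses that subgroup's coefficients and the outcome is drawn
    from the family's error model (gaussian noise, Bernoulli, or Poisson).
    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    data = _draw_partition_variables(spec, rng)

    for p in spec.predictors:
        if p.kind == "normal":
            data[p.name] = p.loc + p.scale * rng.standard_normal(spec.n)
        elif p.kind == "uniform":
            data[p.name] = rng.uniform(p.loc, p.loc + p.scale, size=spec.n)
        else:
            raise InputError(f"unknown predictor kind {p.kind!r}")
    if spec.n_treatment_groups > 1:
        group = rng.integers(1, spec.n_treatment_groups + 1, size=spec.n)
        data["treatment_group"] = group
        for j in range(2, spec.n_treatment_groups + 1):
            data[f"T{j}"] = (group == j).astype(float)

    match = np.zeros(spec.n, dtype=int)
    labels = np.empty(spec.n, dtype=object)
    eta = np.zeros(spec.n)
    X = np.column_stack(
        [np.ones(spec.n)] + [np.asarray(data[c], dtype=float) for c in spec.predictor_names]
    )
    for rule in spec.subgroup_rules:
        mask = np.asarray(rule.predicate(data), dtype=bool)
        match += mask
        labels[mask] = rule.label
        coef = np.asarray(rule.coefficients, dtype=float)
        if coef.shape != (spec.n_coefficients,):
            raise InputError(
                f"rule {rule.label!r} has {coef.size} coefficients, expected "
                f"{spec.n_coefficients}"
            )
        eta[mask] = X[mask] @ coef
    if (match != 1).any():
        raise InputError(
            "subgroup rules must partition the covariate space: "
            f"{int((match != 1).sum())} row(s) matched {sorted(set(match) - {1})} rules"
        )

    if spec.family == GAUSSIAN:
        y = eta + rng.normal(0.0, spec.noise_sd, size=spec.n)
    elif spec.family == BINOMIAL:
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        y = rng.binomial(1, prob).astype(float)
    else:
        y = rng.poisson(np.exp(np.clip(eta, -30, 30))).astype(float)
    data.insert(0, "y", y)

    truth = TruthRecord(
        subgroup_labels=labels,
        coefficients={r.label: tuple(r.coefficients) for r in spec.subgroup_rules},
        informative_variables=spec.informative_variables,
    )
    return data, truth


# ---------------------------------------------------------------------------
# Named fixture specs
# ---------------------------------------------------------------------------


def two_subgroup_gaussian_spec(
    n: int = 500,
    noise_sd: float = 0.5,
    n_noise_variables: int = 9,
    seed: int = 0,
) -> SubgroupDataSpec:
    """Two subgroups split on z01 at 0, slopes +1 and -1 in x, gaussian noise.

    z02..z10 are pure-noise partition variables; only z01 is informative.
    """
    zs = [PartitionVariableSpec(f"z{i:02d}") for i in range(1, n_noise_variables + 2)]
    return SubgroupDataSpec(
        n=n,
        family=GAUSSIAN,
        predictors=(PredictorSpec("x"),),
        n_treatment_groups=0,
        partition_variables=tuple(zs),
        subgroup_rules=(
            SubgroupRule("left", lambda d: np.asarray(d["z01"]) <= 0.0, (0.0, 1.0)),
            SubgroupRule("right", lambda d: np.asarray(d["z01"]) > 0.0, (0.0, -1.0)),
        ),
        informative_variables=("z01",),
        noise_sd=noise_sd,
        seed=seed,
    )


def poisson_two_subgroup_spec(n: int = 600, seed: int = 0) -> SubgroupDataSpec:
    """Count outcome with a rate ratio flip between two subgroups on z01."""
    zs = [PartitionVariableSpec(f"z{i:02d}") for i in range(1, 6)]
    return SubgroupDataSpec(
        n=n,
        family=POISSON,
        predictors=(PredictorSpec("x", scale=0.5),),
        n_treatment_groups=0,
        partition_variables=tuple(zs),
        subgroup_rules=(
            SubgroupRule("low", lambda d: np.asarray(d["z01"]) <= 0.0, (0.5, 0.8)),
            SubgroupRule("high", lambda d: np.asarray(d["z01"]) > 0.0, (1.5, -0.8)),
        ),
        informative_variables=("z01",),
        seed=seed,
    )


def _combine_like_rules() -> tuple[SubgroupRule, ...]:
    """8 subgroups from a depth-3 tree over z01..z05.

    Left branch (z01<=0) refines on z02 then z04; right branch on z03 then
    z05 — all five variables are informative.  Coefficients: intercept and
    treatment-effect patterns differ across subgroups; the baseline-severity
    slope is common.
    """
    base_slope = -0.03  # per percentage point of baseline drinking days

    def coefs(intercept: float, tx_sign: float) -> tuple[float, ...]:
        # 7 treatment effects alternating around +-tx_sign
        tx = tuple(tx_sign * e for e in (1.0, -0.6, 0.8, -0.8, 0.6, -1.0, 0.9))
        return (intercept, base_slope) + tx

    def pred(z1s, z2name, z2s, z3name, z3s):
        def f(d: pd.DataFrame) -> np.ndarray:
            z1 = np.asarray(d["z01"]) <= 0.0
            m1 = z1 if z1s else ~z1
            z2 = np.asarray(d[z2name]) <= 0.0
            m2 = z2 if z2s else ~z2
            z3 = np.asarray(d[z3name]) <= 0.0
            m3 = z3 if z3s else ~z3
            return m1 & m2 & m3

        return f

    rules = []
    k = 0
    for z1s in (True, False):
        z2name = "z02" if z1s else "z03"
        z3name = "z04" if z1s else "z05"
        for z2s in (True, False):
            for z3s in (True, False):
                k += 1
                intercept = (-1.5, -0.5, 0.5, 1.5)[(k - 1) % 4]
                tx_sign = 1.0 if (k % 2 == 0) else -1.0
                rules.append(
                    SubgroupRule(
                        f"g{k}",
                        pred(z1s, z2name, z2s, z3name, z3s),
                        coefs(intercept, tx_sign),
                    )
                )
    return tuple(rules)


def combine_like_demo_spec(n: int = 987, seed: int = 0) -> SubgroupDataSpec:
    """Binomial treatment-effect design echoing an 8-arm alcohol-dependence
    trial: outcome is a 0/1 responder indicator, the node model has a
    baseline-severity covariate plus 7 reference-coded treatment dummies,
    and 40 partition variables of which 5 carry the subgroup structure.
    """
    zs = [PartitionVariableSpec(f"z{i:02d}") for i in range(1, 36)]
    zs += [
        PartitionVariableSpec(f"c{i}", kind="categorical", levels=("A", "B", "C"))
        for i in range(1, 6)
    ]
    return SubgroupDataSpec(
        n=n,
        family=BINOMIAL,
        predictors=(PredictorSpec("baseline_pdd", kind="uniform", loc=0.0, scale=100.0),),
        n_treatment_groups=8,
        partition_variables=tuple(zs),
        subgroup_rules=_combine_like_rules(),
        informative_variables=("z01", "z02", "z03", "z04", "z05"),
        seed=seed,
    )


FIXTURES: dict[str, Callable[..., SubgroupDataSpec]] = {
    "two_subgroup_gaussian": two_subgroup_gaussian_spec,
    "poisson_two_subgroup": poisson_two_subgroup_spec,
    "combine_like": combine_like_demo_spec,
}


def fixture_spec(name: str, **overrides) -> SubgroupDataSpec:
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise InputError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return factory(**overrides)
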