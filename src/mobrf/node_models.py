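"""Parametric node models fitted inside every tree node.

Three families are supported: gaussian with identity link (ordinary least
squares), binomial with logit link (logistic regression) and poisson with
log link.  Fits are maximum likelihood via ordinary least squares or IRLS.
The per-observation score contributions (estimating functions) evaluated at
the fitted coefficients feed the parameter-instability test that drives
split-variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SingularFitError

GAUSSIAN = "gaussian_identity"
BINOMIAL = "binomial_logit"
POISSON = "poisson_log"

FAMILIES = (GAUSSIAN, BINOMIAL, POISSON)

_FAMILY_ALIASES = {
    "gaussian": GAUSSIAN,
    "linear": GAUSSIAN,
    GAUSSIAN: GAUSSIAN,
    "binomial": BINOMIAL,
    "logistic": BINOMIAL,
    BINOMIAL: BINOMIAL,
    "poisson": POISSON,
    POISSON: POISSON,
}

_MAX_IRLS_ITER = 25
_IRLS_TOL = 1e-10
_ETA_CLIP = 30.0


def canonical_family(family: str) -> str:
    try:
        return _FAMILY_ALIASES[family.strip().lower()]
    except KeyError:
        raise InputError(
            f"unknown family {family!r}; choose one of gaussian, binomial, poisson"
        ) from None


@dataclass(frozen=True)
class NodeModelSpec:
    """Outcome, predictors and family of the within-node regression."""

    outcome_name: str
    predictor_names: tuple[str, ...]
    family: str = GAUSSIAN

    def __post_init__(self):
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        object.__setattr__(self, "family", canonical_family(self.family))
        if not self.predictor_names:
            raise InputError("at least one predictor is required")
        if self.outcome_name in self.predictor_names:
            raise InputError(
                f"outcome {self.outcome_name!r} also appears among the predictors"
            )

    @property
    def n_coefficients(self) -> int:
        return 1 + len(self.predictor_names)

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        return ("(Intercept)",) + self.predictor_names


def parse_formula(formula: str, family: str = GAUSSIAN) -> NodeModelSpec:
    """Parse ``"y ~ x1 + x2 + ... + xk"`` into a :class:`NodeModelSpec`.

    Only '+'-separated main effects are supported; whitespace is ignored.
    """
    if "~" not in formula:
        raise InputError(f"formula {formula!r} must contain '~'")
    lhs, rhs = formula.split("~", 1)
    outcome = lhs.strip()
    if not outcome:
        raise InputError(f"formula {formula!r} has an empty left-hand side")
    terms = [t.strip() for t in rhs.split("+")]
    if any(not t for t in terms):
        raise InputError(f"formula {formula!r} has an empty term")
    for t in terms:
        if any(ch in t for ch in "*:()^."):
            raise InputError(
                f"term {t!r} not supported: only '+'-separated main effects are allowed"
            )
    return NodeModelSpec(outcome, tuple(terms), family)


@dataclass(frozen=True)
class FittedNodeModel:
    """Coefficients of a node model: intercept first, then predictors in spec order."""

    spec: NodeModelSpec
    coefficients: np.ndarray
    n_fit: int
    converged: bool = True

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.shape != (self.spec.n_coefficients,):
            raise InputError(
                f"expected {self.spec.n_coefficients} coefficients, got {coef.shape}"
            )


def design_matrix(spec: NodeModelSpec, rows: pd.DataFrame) -> np.ndarray:
    """Intercept column followed by the predictors in spec order."""
    missing = [c for c in spec.predictor_names if c not in rows.columns]
    if missing:
        raise InputError(f"missing predictor column(s): {missing}")
    X = np.empty((len(rows), spec.n_coefficients), dtype=float)
    X[:, 0] = 1.0
    for j, name in enumerate(spec.predictor_names, start=1):
        X[:, j] = np.asarray(rows[name], dtype=float)
    return X


def _outcome_vector(spec: NodeModelSpec, rows: pd.DataFrame) -> np.ndarray:
    if spec.outcome_name not in rows.columns:
        raise InputError(f"missing outcome column {spec.outcome_name!r}")
    y = np.asarray(rows[spec.outcome_name], dtype=float)
    if np.isnan(y).any():
        raise InputError(f"outcome {spec.outcome_name!r} contains missing values")
    if spec.family == BINOMIAL and not np.isin(y, (0.0, 1.0)).all():
        raise InputError(
            f"binomial outcome {spec.outcome_name!r} must be coded 0/1"
        )
    if spec.family == POISSON and ((y < 0).any() or (y != np.floor(y)).any()):
        raise InputError(
            f"poisson outcome {spec.outcome_name!r} must be a non-negative integer"
        )
    return y


def _mean_fn(family: str, eta: np.ndarray) -> np.ndarray:
    if family == GAUSSIAN:
        return eta
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == BINOMIAL:
        return 1.0 / (1.0 + np.exp(-eta))
    return np.exp(eta)  # poisson


def _solve_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError("rank-deficient design in least-squares fit")
    return coef


def fit_irls(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    start: np.ndarray | None = None,
    max_iter: int = _MAX_IRLS_ITER,
) -> tuple[np.ndarray, bool]:
    """IRLS for the canonical-link binomial / poisson GLM.

    Returns (coefficients, converged).  Raises SingularFitError when the
    weighted normal equations are numerically singular.
    """
    n, k = X.shape
    beta = np.zeros(k) if start is None else np.array(start, dtype=float)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = _mean_fn(family, eta)
        if family == BINOMIAL:
            w = mu * (1.0 - mu)
        else:
            w = mu
        w = np.maximum(w, 1e-10)
        # working response z = eta + (y - mu) / w ; solve X'WX beta = X'Wz
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWz = Xw.T @ eta + X.T @ (y - mu)
        try:
            c = np.linalg.cholesky(XtWX)
        except np.linalg.LinAlgError:
            raise SingularFitError("singular weighted design in IRLS") from None
        new = np.linalg.solve(c.T, np.linalg.solve(c, XtWz))
        if np.max(np.abs(new - beta)) < _IRLS_TOL * (1.0 + np.max(np.abs(beta))):
            return new, True
        beta = new
    return beta, False


def fit_node_model(
    spec: NodeModelSpec,
    rows: pd.DataFrame,
    start: np.ndarray | None = None,
) -> FittedNodeModel:
    """Maximum-likelihood fit of the node model on ``rows``.

    Gaussian is fit by least squares; binomial and poisson by IRLS with a
    25-iteration cap (hitting the cap is flagged with ``converged=False``).
    Missing values and wrong outcome coding raise :class:`InputError`;
    a rank-deficient design raises :class:`SingularFitError`.
    """
    X = design_matrix(spec, rows)
    if np.isnan(X).any():
        raise InputError("predictor columns contain missing values")
    y = _outcome_vector(spec, rows)
    if len(y) < spec.n_coefficients:
        raise SingularFitError(
            f"{len(y)} rows cannot identify {spec.n_coefficients} coefficients"
        )
    if spec.family == GAUSSIAN:
        coef = _solve_ols(X, y)
        converged = True
    else:
        coef, converged = fit_irls(X, y, spec.family, start=start)
    return FittedNodeModel(spec, coef, n_fit=len(y), converged=converged)


def predict_response(model: FittedNodeModel, rows: pd.DataFrame) -> np.ndarray:
    """Fitted responses on the response scale.

    Gaussian returns the linear predictor, binomial the inverse-logit
    probability and poisson the exponentiated linear predictor.
    """
    X = design_matrix(model.spec, rows)
    return _mean_fn(model.spec.family, X @ model.coefficients)


def estimating_functions(model: FittedNodeModel, rows: pd.DataFrame) -> np.ndarray:
    """Per-observation score contributions at the fitted coefficients.

    For all three canonical-link families the contribution of observation i
    is ``(y_i - mu_i) * x_i``, an ``n x k`` matrix whose column sums over the
    fitting sample vanish (first-order condition).
    """
    X = design_matrix(model.spec, rows)
    y = _outcome_vector(model.spec, rows)
    mu = _mean_fn(model.spec.family, X @ model.coefficients)
    return (y - mu)[:, None] * X


def log_likelihood(model: FittedNodeModel, rows: pd.DataFrame) -> float:
    """Maximized log-likelihood contribution used as the split objective.

    Gaussian returns the negative sum of squared errors (a monotone
    transform of the profile likelihood, matching the pooled-SSE split
    objective); binomial and poisson return the log-likelihood kernel.
    """
    X = design_matrix(model.spec, rows)
    y = _outcome_vector(model.spec, rows)
    eta = X @ model.coefficients
    fam = model.spec.family
    if fam == GAUSSIAN:
        r = y - eta
        return -float(r @ r)
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if fam == BINOMIAL:
        return float(y @ eta - np.sum(np.log1p(np.exp(eta))))
    return float(y @ eta - np.sum(np.exp(eta)))
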