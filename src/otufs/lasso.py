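"""Embedded feature selection by l1-penalized least squares on +/-1 labels.

The model is the least-squares lasso

    theta* = argmin_theta (1/2M) ||y - X^T theta||_2^2 + lambda ||theta||_1

with X the K x M (feature-by-sample) relative-abundance matrix, y in
{-1,+1}^M the binary phenotype coding, and K >> M permitted.  The penalty
grid is data-derived: its upper end is lambda_max = (1/M) max_j |X_j . y|,
the smallest penalty whose solution is exactly zero, and lambda is chosen by
stratified cross-validation on the held-out squared-error cost.  Features
with nonzero coefficients form the (data-driven-size) selected support.

The convex subproblems are solved by scikit-learn's coordinate descent,
whose objective matches the formula above; first-order (KKT) optimality is
verified after each fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import StratifiedKFold

from .greedy import SelectionResult
from .io import AbundanceTable, LabelVector

__all__ = [
    "DesignData",
    "LassoModel",
    "LassoOptions",
    "encode_binary_labels",
    "lambda_grid",
    "fit_lasso",
    "cv_select_lambda",
    "lasso_select",
]

ZERO_TOL = 1e-8
KKT_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when a fit does not satisfy first-order optimality."""


@dataclass
class DesignData:
    """Feature-by-sample design X (K x M) and +/-1 response y (length M)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[1] != self.y.size:
            raise ValueError("X must be K x M and y length M")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("y must be coded in {-1, +1}")
        if np.unique(self.y).size < 2:
            raise ValueError("y must contain both classes")


@dataclass
class LassoModel:
    theta: np.ndarray
    lambda_chosen: float
    lambda_grid: np.ndarray
    cv_scores: np.ndarray
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise ValueError("lambda_grid must be strictly descending")
        self.support = np.flatnonzero(np.abs(self.theta) > ZERO_TOL)


@dataclass
class LassoOptions:
    positive_class: str | None = None
    folds: int = 5
    n_values: int = 100
    eps_ratio: float = 1e-4
    seed: int = 0
    standardize: bool = False


def encode_binary_labels(labels: LabelVector, positive_class: str) -> np.ndarray:
    """Map a two-class LabelVector to +/-1 with the named class as +1."""
    if len(labels.classes) != 2:
        raise ValueError(
            "lasso needs exactly two classes; map the phenotype column to two "
            f"labels first (have {labels.classes})"
        )
    if positive_class not in labels.classes:
        raise ValueError(
            f"positive_class {positive_class!r} not among classes {labels.classes}"
        )
    return np.where(np.asarray(labels.values) == positive_class, 1.0, -1.0)


def lambda_grid(data: DesignData, n_values: int = 100, eps_ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced descending grid from lambda_max down to eps_ratio*lambda_max."""
    if n_values < 2:
        raise ValueError("n_values must be >= 2")
    if not 0.0 < eps_ratio < 1.0:
        raise ValueError("eps_ratio must be in (0, 1)")
    m = data.y.size
    lam_max = float(np.max(np.abs(data.X @ data.y)) / m)
    if lam_max == 0.0:
        raise ValueError("lambda_max is 0: every feature is orthogonal to y")
    return np.geomspace(lam_max, eps_ratio * lam_max, n_values)


def _check_kkt(X: np.ndarray, y: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Max violation of the stationarity conditions of the penalized objective."""
    m = y.size
    grad = X @ (y - X.T @ theta) / m  # (1/M) X (y - X^T theta)
    viol_zero = np.max(np.abs(grad[np.abs(theta) <= ZERO_TOL]) - lam, initial=0.0)
    nz = np.abs(theta) > ZERO_TOL
    viol_nz = np.max(np.abs(grad[nz] - lam * np.sign(theta[nz])), initial=0.0)
    return float(max(viol_zero, viol_nz))


def fit_lasso(data: DesignData, lam: float) -> np.ndarray:
    """Solve the penalized least-squares problem at one penalty value."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=100_000, tol=1e-10)
    with warnings.catch_warnings():
        # optimality is verified directly below; the solver's own stopping
        # heuristic is not the authority
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(data.X.T, data.y)
    theta = np.asarray(model.coef_, dtype=float)
    gap = _check_kkt(data.X, data.y, theta, lam)
    if gap > KKT_TOL:
        raise ConvergenceError(
            f"first-order optimality violated by {gap:.3e} at lambda={lam:.3e}"
        )
    return theta


def cv_select_lambda(
    data: DesignData,
    folds: int = 5,
    n_values: int = 100,
    eps_ratio: float = 1e-4,
    seed: int = 0,
) -> LassoModel:
    """Grid search over the data-derived lambda grid with stratified CV.

    The validation cost is the held-out squared error (1/2M_val)
    ||y_val - X_val^T theta||^2; the lambda minimizing the mean cost wins
    (ties to the larger, sparser lambda), and the final model is refit on
    all the data at that lambda.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = lambda_grid(data, n_values, eps_ratio)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    costs = np.zeros((folds, grid.size))
    Xs = data.X.T  # samples x features, sklearn layout
    for f, (tr, va) in enumerate(splitter.split(Xs, data.y)):
        if np.unique(data.y[tr]).size < 2 or np.unique(data.y[va]).size < 2:
            raise ValueError(f"fold {f} lost a class; use fewer folds")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(
                Xs[tr], data.y[tr], alphas=grid, max_iter=10_000, tol=1e-6
            )
        resid = data.y[va][:, None] - Xs[va] @ coefs  # M_val x n_grid
        costs[f] = 0.5 * np.mean(resid**2, axis=0)
    mean_cost = costs.mean(axis=0)
    best = int(np.argmin(mean_cost))  # first minimum -> largest lambda on ties
    lam = float(grid[best])
    theta = fit_lasso(data, lam)
    return LassoModel(theta=theta, lambda_chosen=lam, lambda_grid=grid, cv_scores=mean_cost)


def lasso_select(
    table: AbundanceTable, labels: LabelVector, options: LassoOptions | None = None
) -> SelectionResult:
    """End-to-end embedded selection on an abundance table.

    Counts are converted to per-sample relative abundances, labels to +/-1
    (by default the lexicographically last class is +1), and the support of
    the cross-validated fit is returned ordered by |theta| descending, with
    the fitted coefficients as scores.  The support may be empty.
    """
    options = options or LassoOptions()
    positive = options.positive_class or labels.classes[-1]
    y = encode_binary_labels(labels, positive)
    from .reporting import relative_abundance

    X = relative_abundance(table)
    if options.standardize:
        sd = X.std(axis=1, ddof=0, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    model = cv_select_lambda(
        DesignData(X, y),
        folds=options.folds,
        n_values=options.n_values,
        eps_ratio=options.eps_ratio,
        seed=options.seed,
    )
    order = model.support[np.argsort(-np.abs(model.theta[model.support]), kind="stable")]
    return SelectionResult(
        feature_indices=[int(j) for j in order],
        feature_ids=[table.feature_ids[j] for j in order],
        scores=[float(model.theta[j]) for j in order],
        method=f"lasso(lambda={model.lambda_chosen:.6g}, positive={positive})",
        k=len(order),
    )
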