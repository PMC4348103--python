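"""Closed-form ridge regression with an exact leave-one-out evaluator.

The model is y = Xb fitted by minimizing

    sum_i (y_i - sum_j b_j x_ij)^2  +  lambda * sum_j b_j^2,

whose minimizer is b = (X'X + lambda I)^-1 X'y.  For m > n the equivalent
dual form b = X'(XX' + lambda I)^-1 y is used, which only ever factorizes an
n x n system — the regime of interest here has hundreds more covariates than
samples.  The intercept is handled by centering y (and standardizing X)
rather than by an unpenalized intercept column, which would change the
closed form.

Leave-one-out (drop-one) cross-validation is computed exactly without n
refits via the hat matrix H = X (X'X + lambda I)^-1 X':

    loo_residual_i = residual_i / (1 - h_ii).

Writing K = XX' with eigendecomposition K = U diag(d) U', H has the same
eigenvectors with eigenvalues d/(d + lambda), so a whole lambda ladder is
evaluated from a single factorization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .errors import (
    AllUndefinedError,
    ShapeMismatchError,
    SingularSystemError,
    TooFewRowsError,
)
from .preprocess import StandardizationStats

#: relative threshold below which a vector counts as constant (correlation undefined)
_VAR_TOL = 1e-12


@dataclass
class RidgeModel:
    """Fitted ridge coefficients for one design matrix."""

    coefficients: np.ndarray
    penalty: float
    trait_mean: float = 0.0
    stats: Optional[StandardizationStats] = None


@dataclass
class LooResult:
    """Collated drop-one predictions and their correlation with the data.

    ``cvc`` is the Pearson correlation between observed values and
    leave-one-out predictions; it is NaN with ``defined=False`` when either
    vector is constant — the "failed" outcome, which is data, not an error.
    """

    loo_predictions: np.ndarray
    cvc: float
    defined: bool


def pearson_cvc(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, bool]:
    """Pearson r with an explicit undefined flag for (near-)constant vectors."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(predicted))):
        return float("nan"), False
    so = observed.std()
    sp = predicted.std()
    tol_o = _VAR_TOL * max(1.0, abs(float(observed.mean())))
    tol_p = _VAR_TOL * max(1.0, abs(float(predicted.mean())))
    if so <= tol_o or sp <= tol_p:
        return float("nan"), False
    r = float(np.corrcoef(observed, predicted)[0, 1])
    return r, True


def ridge_objective(
    X: np.ndarray, y: np.ndarray, b: np.ndarray, penalty: float
) -> float:
    """The penalized residual sum of squares the estimator minimizes."""
    resid = y - X @ b
    return float(resid @ resid + penalty * (b @ b))


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    penalty: float,
    trait_mean: float = 0.0,
    stats: Optional[StandardizationStats] = None,
) -> RidgeModel:
    """Closed-form ridge fit; primal for n >= m, dual (kernel) form otherwise.

    ``penalty = 0`` recovers ordinary least squares and is only admissible
    for full-rank tall systems; otherwise :class:`SingularSystemError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ShapeMismatchError("X must be n x m and y length n")
    n, m = X.shape
    if n < 2:
        raise TooFewRowsError("ridge fit needs at least 2 samples")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if penalty == 0.0:
        if m >= n or np.linalg.matrix_rank(X) < m:
            raise SingularSystemError(
                "unpenalized least squares needs more (independent) rows than columns"
            )
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
    elif m <= n:
        A = X.T @ X + penalty * np.eye(m)
        b = scipy.linalg.solve(A, X.T @ y, assume_a="pos")
    else:
        K = X @ X.T + penalty * np.eye(n)
        b = X.T @ scipy.linalg.solve(K, y, assume_a="pos")
    return RidgeModel(coefficients=b, penalty=float(penalty), trait_mean=trait_mean, stats=stats)


def ridge_predict(model: RidgeModel, X_new: np.ndarray) -> np.ndarray:
    """Predict on the original trait scale: X_new b + trait mean."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.coefficients.shape[0]:
        raise ShapeMismatchError("X_new column count does not match the model")
    return X_new @ model.coefficients + model.trait_mean


def _loo_from_kernel(
    K: np.ndarray, y: np.ndarray, penalties: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact LOO for every penalty in a ladder from one eigendecomposition.

    Returns (loo predictions n x L, cvc length L, defined length L) for the
    ridge smoother H(lambda) = K (K + lambda I)^-1.
    """
    penalties = np.asarray(penalties, dtype=float)
    d, U = scipy.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    Uty = U.T @ y
    U2 = U**2
    ratios = d[:, None] / (d[:, None] + penalties[None, :])  # n x L
    fitted = U @ (ratios * Uty[:, None])
    leverage = U2 @ ratios
    loo = y[:, None] - (y[:, None] - fitted) / (1.0 - leverage)
    L = penalties.shape[0]
    cvc = np.empty(L)
    defined = np.empty(L, dtype=bool)
    for k in range(L):
        cvc[k], defined[k] = pearson_cvc(y, loo[:, k])
    return loo, cvc, defined


def loo_evaluate(X: np.ndarray, y: np.ndarray, penalty: float) -> LooResult:
    """Exact drop-one predictions via the hat-matrix shortcut.

    Equals n explicit refits on the same (fixed) X and y; any centering or
    standardization must already be baked into the inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise TooFewRowsError("leave-one-out needs at least 3 samples")
    if penalty <= 0:
        raise ValueError("leave-one-out shortcut requires penalty > 0")
    loo, cvc, defined = _loo_from_kernel(X @ X.T, y, np.array([penalty]))
    return LooResult(loo[:, 0], float(cvc[0]), bool(defined[0]))


def default_lambda_grid(
    n_features: int, num: int = 25, lo: float = 1e-3, hi: float = 1e3
) -> np.ndarray:
    """Log-uniform penalty ladder scaled by the column count.

    Scaling by the number of covariates keeps the per-column shrinkage of
    pooled and single-block searches comparable.
    """
    return np.geomspace(lo * n_features, hi * n_features, num)


def select_lambda(
    X: np.ndarray, y: np.ndarray, penalty_grid: Sequence[float]
) -> tuple[float, LooResult]:
    """Pick the penalty maximizing the drop-one CV correlation.

    Ties prefer the larger penalty (more shrinkage, simpler model).  Grid
    points with undefined correlation score -inf; if every point is
    undefined the selection itself fails with :class:`AllUndefinedError`.
    """
    grid = np.asarray(list(penalty_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    if np.any(grid <= 0) or np.any(np.diff(grid) < 0):
        raise ValueError("penalty grid must be positive and sorted ascending")
    loo, cvc, defined = _loo_from_kernel(np.asarray(X) @ np.asarray(X).T, y, grid)
    if not defined.any():
        raise AllUndefinedError("CV correlation undefined at every grid penalty")
    score = np.where(defined, cvc, -np.inf)
    best = int(np.flatnonzero(score >= score.max())[-1])  # ties -> larger penalty
    return float(grid[best]), LooResult(loo[:, best], float(cvc[best]), True)
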