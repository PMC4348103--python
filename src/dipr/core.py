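"""Differentially penalized regression (DiPR) over two covariate blocks.

Ridge regression applied to markers and metabolites jointly shrinks both
blocks with one penalty, so the more informative block can be over-penalized
and the combined model can lose to the better single block.  DiPR fixes this
with block-specific penalties lambda_a, lambda_b:

    sum_i (y_i - X1_i b - X2_i b*)^2
        + lambda_a ||b||^2 + lambda_b ||b*||^2

realized with *standard* ridge software by rescaling the blocks with weights
w and 1 - w and fitting a single penalty lambda; a regression on c*x with
coefficient beta is identical to a regression on x with coefficient c*beta,
so the rescaling just redistributes the shrinkage.  Two scaling conventions
are provided:

``sqrt-w``  (default)
    columns scaled by sqrt(w) and sqrt(1-w); a single-penalty ridge on the
    scaled matrix then minimizes exactly the objective above with
    lambda_a = lambda/w and lambda_b = lambda/(1-w).

``paper-w``
    columns scaled by w and 1-w, the literal description of the rescaling;
    the implied penalties are lambda/w^2 and lambda/(1-w)^2.

The two conventions trace the same family of (lambda_a, lambda_b) ratios,
just parametrized differently, so a full (w, lambda) grid search reaches the
same models under either.

Hyperparameters are chosen by exhaustive grid search maximizing the drop-one
cross-validation correlation (CVC), and honest accuracy is measured by a
nested drop-one protocol: each sample is set aside in turn, the grid search
runs by drop-one CV within the remaining samples, the model is refitted at
the selected (w, lambda) and predicts the held-out sample; the collated
out-of-fold predictions are correlated with the observations.  At w = 1 or
w = 0 the method reduces to single-block ridge, and at w = 0.5 to pooled
ridge, so for a *fixed* training set the searched CVC can never fall below
those special cases — but under the nested protocol this guarantee no
longer holds and DiPR can fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AllUndefinedError, ShapeMismatchError, WOutOfRangeError
from .preprocess import standardize_apply, standardize_fit
from .ridge import (
    LooResult,
    _loo_from_kernel,
    default_lambda_grid,
    pearson_cvc,
    ridge_fit,
)

CONVENTIONS = ("sqrt-w", "paper-w")
METHODS = ("block1", "block2", "pooled", "dipr")

#: fixed w restriction implementing each comparison method
_METHOD_W_GRID = {"block1": (1.0,), "block2": (0.0,), "pooled": (0.5,)}


def block_scales(w: float, convention: str = "sqrt-w") -> tuple[float, float]:
    """Column scale factors (c1, c2) for blocks 1 and 2 at weight ``w``."""
    if not 0.0 <= w <= 1.0:
        raise WOutOfRangeError(f"w={w} outside [0, 1]")
    if convention == "sqrt-w":
        return math.sqrt(w), math.sqrt(1.0 - w)
    if convention == "paper-w":
        return float(w), float(1.0 - w)
    raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")


def effective_penalties(
    w: float, penalty: float, convention: str = "sqrt-w"
) -> tuple[float, float]:
    """Block-wise penalties (lambda_a, lambda_b) implied by (w, lambda)."""
    c1, c2 = block_scales(w, convention)
    la = penalty / c1**2 if c1 > 0 else math.inf
    lb = penalty / c2**2 if c2 > 0 else math.inf
    return la, lb


def scale_blocks(
    X1: np.ndarray, X2: np.ndarray, w: float, convention: str = "sqrt-w"
) -> np.ndarray:
    """Concatenate [c1(w) * X1 | c2(w) * X2] for single-penalty ridge."""
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape[0] != X2.shape[0]:
        raise ShapeMismatchError("blocks must have the same number of rows")
    c1, c2 = block_scales(w, convention)
    return np.hstack([c1 * X1, c2 * X2])


def default_w_grid(step: float = 0.05) -> np.ndarray:
    """Weights from 0 to 1 inclusive in steps of ``step`` (default 21 values)."""
    n = round(1.0 / step)
    return np.linspace(0.0, 1.0, n + 1)


@dataclass
class DiprModel:
    """A fitted two-block ridge model on the original standardized scale.

    Coefficients are mapped back from the rescaled design, so predictions
    are convention-independent given the same (lambda_a, lambda_b).
    """

    w: float
    penalty: float
    coef_block1: np.ndarray
    coef_block2: np.ndarray
    convention: str
    trait_mean: float = 0.0

    @property
    def penalties(self) -> tuple[float, float]:
        return effective_penalties(self.w, self.penalty, self.convention)

    def predict(self, X1_new: np.ndarray, X2_new: np.ndarray) -> np.ndarray:
        X1_new = np.asarray(X1_new, dtype=float)
        X2_new = np.asarray(X2_new, dtype=float)
        if (
            X1_new.shape[1] != self.coef_block1.shape[0]
            or X2_new.shape[1] != self.coef_block2.shape[0]
        ):
            raise ShapeMismatchError("new blocks do not match model dimensions")
        return (
            X1_new @ self.coef_block1 + X2_new @ self.coef_block2 + self.trait_mean
        )


def dipr_fit(
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    w: float,
    penalty: float,
    convention: str = "sqrt-w",
    trait_mean: float = 0.0,
) -> DiprModel:
    """Fit the two-block model at fixed (w, lambda) via rescaled ridge.

    At the boundaries w = 0 / w = 1 the zero-weight block is dropped from
    the fit (its coefficients are exactly zero), avoiding any division by a
    vanishing scale factor.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    c1, c2 = block_scales(w, convention)
    m1, m2 = X1.shape[1], X2.shape[1]
    if c1 == 0.0:
        b2 = ridge_fit(X2, y, penalty).coefficients
        return DiprModel(w, float(penalty), np.zeros(m1), b2, convention, trait_mean)
    if c2 == 0.0:
        b1 = ridge_fit(X1, y, penalty).coefficients
        return DiprModel(w, float(penalty), b1, np.zeros(m2), convention, trait_mean)
    scaled = scale_blocks(X1, X2, w, convention)
    beta = ridge_fit(scaled, y, penalty).coefficients
    return DiprModel(
        w, float(penalty), c1 * beta[:m1], c2 * beta[m1:], convention, trait_mean
    )


@dataclass
class GridSearchResult:
    """Outcome of the exhaustive (w, lambda) search on one training set."""

    w: float
    penalty: float
    loo: LooResult
    cvc_grid: np.ndarray  # len(w_grid) x len(lambda_grid); NaN where undefined
    w_grid: np.ndarray
    lambda_grid: np.ndarray


def _better(
    cand: tuple[float, float, float], best: tuple[float, float, float]
) -> bool:
    """Deterministic ordering on (cvc, penalty, w) candidates.

    Higher CVC wins; ties prefer the larger penalty, then the w nearest
    0.5, then the smaller w.
    """
    cvc, lam, w = cand
    bcvc, blam, bw = best
    if cvc != bcvc:
        return cvc > bcvc
    if lam != blam:
        return lam > blam
    if abs(w - 0.5) != abs(bw - 0.5):
        return abs(w - 0.5) < abs(bw - 0.5)
    return w < bw


def dipr_search(
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    w_grid: Optional[Sequence[float]] = None,
    lambda_grid: Optional[Sequence[float]] = None,
    convention: str = "sqrt-w",
) -> GridSearchResult:
    """Exhaustive drop-one CV over the full (w, lambda) grid.

    For each w the n x n Gram matrix w-combination is eigendecomposed once
    and the whole penalty ladder evaluated from it, so the search costs
    len(w_grid) small eigendecompositions rather than a refit per cell.
    Raises :class:`AllUndefinedError` if no grid cell yields a defined CVC.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    if w_grid is None:
        w_grid = default_w_grid()
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X1.shape[1] + X2.shape[1])
    w_arr = np.asarray(list(w_grid), dtype=float)
    lam_arr = np.asarray(list(lambda_grid), dtype=float)
    if np.any((w_arr < 0) | (w_arr > 1)):
        raise WOutOfRangeError("w grid must lie in [0, 1]")
    if np.any(lam_arr <= 0):
        raise ValueError("penalty grid must be positive")

    K1 = X1 @ X1.T
    K2 = X2 @ X2.T
    cvc_grid = np.full((w_arr.size, lam_arr.size), np.nan)
    best_key = None
    best_loo = None
    for i, w in enumerate(w_arr):
        c1, c2 = block_scales(w, convention)
        K = c1 * c1 * K1 + c2 * c2 * K2
        loo, cvc, defined = _loo_from_kernel(K, y, lam_arr)
        cvc_grid[i, defined] = cvc[defined]
        for k in np.flatnonzero(defined):
            cand = (float(cvc[k]), float(lam_arr[k]), float(w))
            if best_key is None or _better(cand, best_key):
                best_key = cand
                best_loo = LooResult(loo[:, k].copy(), float(cvc[k]), True)
    if best_key is None:
        raise AllUndefinedError("CV correlation undefined over the entire grid")
    best_cvc, best_lam, best_w = best_key
    return GridSearchResult(best_w, best_lam, best_loo, cvc_grid, w_arr, lam_arr)


@dataclass
class NestedCvResult:
    """Honest out-of-fold accuracy of one method on one trait.

    ``status`` is "failed" (with ``cvc`` NaN) when the collated predictions
    or the observations are constant — mirroring how a completely
    unpredictable trait is reported rather than raised.
    """

    method: str
    observed: np.ndarray
    oof_predictions: np.ndarray
    cvc: float
    status: str  # "ok" or "failed"
    per_fold_w: np.ndarray
    per_fold_penalty: np.ndarray

    @property
    def mean_w(self) -> float:
        if np.all(np.isnan(self.per_fold_w)):
            return float("nan")
        return float(np.nanmean(self.per_fold_w))


def _normalize_method(method: str) -> str:
    method = method.replace("-only", "")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return method


def nested_cv_evaluate(
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    method: str = "dipr",
    w_grid: Optional[Sequence[float]] = None,
    lambda_grid: Optional[Sequence[float]] = None,
    standardization_mode: str = "training-fold",
    convention: str = "sqrt-w",
) -> NestedCvResult:
    """Nested drop-one evaluation of one method.

    ``X1`` and ``X2`` are *raw* (post-QC) covariate blocks, possibly with
    missing entries; standardization happens inside, either per training
    fold (default, leakage-free) or once on the full data.  The trait is
    centered with the training-fold mean and predictions are returned on
    the original trait scale.

    The single-block and pooled comparison methods are the w = 1, w = 0 and
    w = 0.5 restrictions of the same machinery, so their protocol (inner
    drop-one penalty search, refit, outer prediction) is identical to
    DiPR's by construction.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("nested drop-one evaluation needs at least 4 samples")
    if standardization_mode not in ("training-fold", "full-data"):
        raise ValueError(f"unknown standardization_mode {standardization_mode!r}")
    method = _normalize_method(method)
    if method != "dipr":
        w_grid = _METHOD_W_GRID[method]
    elif w_grid is None:
        w_grid = default_w_grid()
    if lambda_grid is None:
        m_active = {"block1": X1.shape[1], "block2": X2.shape[1]}.get(
            method, X1.shape[1] + X2.shape[1]
        )
        lambda_grid = default_lambda_grid(m_active)

    if standardization_mode == "full-data":
        Z1_full, _ = standardize_fit(X1, source="full-data")
        Z2_full, _ = standardize_fit(X2, source="full-data")

    preds = np.empty(n)
    per_w = np.full(n, np.nan)
    per_lam = np.full(n, np.nan)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if standardization_mode == "training-fold":
            Z1, s1 = standardize_fit(X1[tr])
            Z2, s2 = standardize_fit(X2[tr])
            z1_i = standardize_apply(X1[i : i + 1], s1)
            z2_i = standardize_apply(X2[i : i + 1], s2)
        else:
            Z1, Z2 = Z1_full[tr], Z2_full[tr]
            z1_i, z2_i = Z1_full[i : i + 1], Z2_full[i : i + 1]
        y_mean = float(y[tr].mean())
        y_tr = y[tr] - y_mean
        try:
            res = dipr_search(Z1, Z2, y_tr, w_grid, lambda_grid, convention)
        except AllUndefinedError:
            preds[i] = y_mean  # no informative model; fall back to the fold mean
            continue
        model = dipr_fit(Z1, Z2, y_tr, res.w, res.penalty, convention)
        preds[i] = float(model.predict(z1_i, z2_i)[0]) + y_mean
        per_w[i] = res.w
        per_lam[i] = res.penalty

    cvc, defined = pearson_cvc(y, preds)
    return NestedCvResult(
        method=method,
        observed=y.copy(),
        oof_predictions=preds,
        cvc=cvc,
        status="ok" if defined else "failed",
        per_fold_w=per_w,
        per_fold_penalty=per_lam,
    )
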