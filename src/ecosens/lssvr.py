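"""Least-squares support vector regression (LS-SVR) with an RBF kernel.

LS-SVR is ridge-penalized kernel regression: the training problem reduces
to a single symmetric positive-definite linear system rather than a
quadratic program, so fitting is a closed-form solve.  With Gram matrix
``Omega[i, j] = K(x_i, x_j)`` and ``A = Omega + I / gamma`` the dual
solution is

    b     = 1' A^{-1} y / (1' A^{-1} 1)
    alpha = A^{-1} (y - b 1)

and predictions are ``yhat(x) = sum_i alpha_i K(x, x_i) + b``.  ``gamma``
is the regularization weight (larger gamma = weaker regularization);
``sigma`` is the RBF width ``K(x, x') = exp(-||x - x'||^2 / (2 sigma^2))``.

Every training point carries a dual coefficient (LS-SVR has no sparsity),
so the "support vectors" are simply all ``m`` training rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "LSSVR",
    "LSSVRResults",
    "rbf_kernel",
    "gram_matrix",
    "fit",
    "predict",
    "insample_objective",
]


@dataclass(frozen=True)
class KernelParams:
    """RBF width ``sigma`` and regularization weight ``gamma``, both > 0."""

    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be a positive finite real, got {self.sigma}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"gamma must be a positive finite real, got {self.gamma}")


def rbf_kernel(x: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """Gaussian kernel ``exp(-||x - x2||^2 / (2 sigma^2))`` for two vectors."""
    x = np.asarray(x, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {x2.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x - x2) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def gram_matrix(X: np.ndarray, sigma: float) -> np.ndarray:
    """Pairwise RBF kernel matrix over the rows of ``X`` (symmetric, unit
    diagonal, positive semidefinite)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = cdist(X, X, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def _cross_kernel(Xq: np.ndarray, X: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(np.atleast_2d(Xq), np.atleast_2d(X), metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


class LSSVR:
    """LS-SVR model over a fixed training sample.

    Parameters
    ----------
    endog : (m,) array_like
        Response values.
    exog : (m, d) array_like
        Predictor matrix.  No internal standardization is applied; scale
        the columns beforehand if they live on incommensurate units.
    """

    def __init__(self, endog, exog):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"endog has {y.shape[0]} rows but exog has {X.shape[0]}"
            )
        if y.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
            raise ValueError("endog/exog must be finite")
        self.endog = y
        self.exog = X
        self.nobs = y.shape[0]

    def fit(self, params: KernelParams | None = None, *, sigma: float | None = None,
            gamma: float | None = None) -> "LSSVRResults":
        """Solve the dual system for ``(alpha, b)`` at the given kernel
        parameters.  ``A = Omega + I/gamma`` is symmetric positive definite
        for every gamma > 0, so a Cholesky solve applies; no iteration."""
        if params is None:
            params = KernelParams(sigma=sigma, gamma=gamma)
        m = self.nobs
        omega = gram_matrix(self.exog, params.sigma)
        A = omega + np.eye(m) / params.gamma
        try:
            c, low = cho_factor(A, lower=True, check_finite=False)
        except LinAlgError as exc:  # pragma: no cover - pathological inputs
            raise np.linalg.LinAlgError(
                "A = Omega + I/gamma is numerically singular (duplicate rows "
                "with very large gamma?); reduce gamma or jitter the data"
            ) from exc
        ones = np.ones(m)
        a_inv_y = cho_solve((c, low), self.endog, check_finite=False)
        a_inv_1 = cho_solve((c, low), ones, check_finite=False)
        b = float(ones @ a_inv_y) / float(ones @ a_inv_1)
        alpha = a_inv_y - b * a_inv_1
        return LSSVRResults(self, params, alpha, b, omega=omega)


class LSSVRResults:
    """Fitted LS-SVR: dual coefficients ``alpha``, intercept ``b`` and the
    kernel parameters, with prediction and diagnostics."""

    def __init__(self, model: LSSVR, params: KernelParams, alpha: np.ndarray,
                 intercept: float, omega: np.ndarray | None = None):
        self.model = model
        self.params = params
        self.alpha = np.asarray(alpha, dtype=float)
        self.intercept = float(intercept)
        self._omega = omega

    # -- spec-facing aliases -------------------------------------------------
    @property
    def X_train(self) -> np.ndarray:
        return self.model.exog

    @property
    def b(self) -> float:
        return self.intercept

    def predict(self, Xq) -> np.ndarray:
        """``yhat_j = sum_i alpha_i K(x_j, x_i) + b`` for each query row."""
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if Xq.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"query has {Xq.shape[1]} features, model trained on "
                f"{self.model.exog.shape[1]}"
            )
        K = _cross_kernel(Xq, self.model.exog, self.params.sigma)
        return K @ self.alpha + self.intercept

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def kkt_residuals(self) -> tuple[float, float]:
        """Max-norm residuals of the two dual optimality conditions:
        ``(Omega + I/gamma) alpha + b 1 - y`` and ``1' alpha``."""
        m = self.model.nobs
        omega = self._omega
        if omega is None:
            omega = gram_matrix(self.model.exog, self.params.sigma)
        r1 = omega @ self.alpha + self.alpha / self.params.gamma \
            + self.intercept - self.model.endog
        r2 = float(np.sum(self.alpha))
        return float(np.max(np.abs(r1))), abs(r2)

    def summary(self) -> str:
        g = float(np.mean(self.resid**2))
        k1, k2 = self.kkt_residuals()
        lines = [
            "LS-SVR Results",
            "=" * 46,
            f"No. observations      {self.model.nobs:>12d}",
            f"No. predictors        {self.model.exog.shape[1]:>12d}",
            f"sigma (RBF width)     {self.params.sigma:>12.6g}",
            f"gamma (regulariz.)    {self.params.gamma:>12.6g}",
            f"intercept b           {self.intercept:>12.6g}",
            f"in-sample MSE G       {g:>12.6g}",
            f"max |KKT residual|    {max(k1, k2):>12.3g}",
            "=" * 46,
        ]
        return "\n".join(lines)


# -- functional surface ------------------------------------------------------

def fit(X, y, params: KernelParams) -> LSSVRResults:
    """Closed-form LS-SVR fit; functional alias for ``LSSVR(y, X).fit``."""
    return LSSVR(y, X).fit(params)


def predict(model: LSSVRResults, Xq) -> np.ndarray:
    return model.predict(Xq)


def insample_objective(X, y, params: KernelParams) -> float:
    """Training objective ``G(sigma, gamma)``: the mean squared residual of
    the model refit at these parameters, evaluated on its own training rows."""
    res = fit(X, y, params)
    r = np.asarray(y, dtype=float).ravel() - res.predict(X)
    return float(np.mean(r**2))
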