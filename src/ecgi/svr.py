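"""Gaussian-kernel ε-insensitive support vector regression in dual form.

The regressor here is the workhorse of both halves of the method: with
ε > 0 it is the ordinary ε-SVR used to map scaled body-surface potentials
to transmembrane potentials, and with ε = 0 its loss degenerates to the
Laplacian (absolute-error) loss used inside the alternating
maximum-margin-clustering solver.

Training solves the standard dual quadratic program

    max_{α, α*}  -1/2 (α-α*)^T K (α-α*) + y^T (α-α*) - ε Σ(α_i+α_i*)
    s.t.  Σ(α_i-α_i*) = 0,   0 <= α_i, α_i* <= C,

via libsvm's SMO (through scikit-learn), and the fitted model is exposed in
dual form: support inputs, dual coefficients β_i = α_i - α_i*, and bias b,
so that f(x) = Σ β_i K(x_i, x) + b with the Gaussian kernel
K(x_i, x_j) = exp(-||x_i-x_j||² / 2σ²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR as _LibsvmSVR
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateInputError, SolverError, ValidationError

__all__ = [
    "SvrHyperparams",
    "ScalingSpec",
    "GaussianSVR",
    "MultiOutputGaussianSVR",
    "gaussian_kernel",
    "gaussian_gram",
    "scale_bsp",
    "scale_bsp_columns",
    "train_svr",
    "predict_svr",
    "train_multi_output",
    "dual_objective",
]


@dataclass(frozen=True)
class SvrHyperparams:
    """SVR hyperparameters: box constraint C, kernel bandwidth σ and tube
    half-width ε (ε = 0 gives the Laplacian loss)."""

    C: float = 1.0
    sigma: float = 1.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be > 0")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")


@dataclass(frozen=True)
class ScalingSpec:
    """Min/max of one BSP time-instant vector, as used by the per-instant
    scaling to (0, 1)."""

    vmin: float
    vmax: float


# ---------------------------------------------------------------------------
# kernel and scaling
# ---------------------------------------------------------------------------


def gaussian_kernel(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """K(x_i, x_j) = exp(-||x_i - x_j||² / (2σ²)), in (0, 1]."""
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    if xi.shape != xj.shape:
        raise ValidationError("kernel arguments must have equal dimension")
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def gaussian_gram(X: np.ndarray, Z: np.ndarray | None = None,
                  sigma: float = 1.0) -> np.ndarray:
    """Gram matrix of the Gaussian kernel between rows of X and Z."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = X if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    d2 = cdist(X, Z, "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma * sigma))


def scale_bsp(bsp_column: np.ndarray) -> tuple[np.ndarray, ScalingSpec]:
    """Min-max scale one time-instant BSP vector to [0, 1].

    Raises DegenerateInputError on a constant vector (zero denominator)."""
    v = np.asarray(bsp_column, dtype=float).ravel()
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise DegenerateInputError("constant BSP vector cannot be min-max scaled")
    return (v - vmin) / (vmax - vmin), ScalingSpec(vmin, vmax)


def scale_bsp_columns(bsps: np.ndarray) -> np.ndarray:
    """Apply the per-instant scaling to every column of a leads x times BSP
    matrix; each column uses its own extrema."""
    bsps = np.asarray(bsps, dtype=float)
    vmin = bsps.min(axis=0, keepdims=True)
    vmax = bsps.max(axis=0, keepdims=True)
    rng = vmax - vmin
    if np.any(rng <= 0):
        raise DegenerateInputError("constant BSP column cannot be min-max scaled")
    return (bsps - vmin) / rng


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class GaussianSVR(BaseEstimator, RegressorMixin):
    """ε-insensitive support vector regressor with Gaussian kernel.

    Parameters
    ----------
    C : float
        Box constraint (trade-off between flatness and training error).
    sigma : float
        Kernel bandwidth σ; the libsvm gamma is 1/(2σ²).
    epsilon : float
        Tube half-width; 0 gives the Laplacian (absolute-error) loss.
    tol : float
        SMO duality-gap stopping tolerance.

    Attributes
    ----------
    support_inputs_ : ndarray of shape (n_sv, d)
        Retained training inputs.
    dual_coefficients_ : ndarray of shape (n_sv,)
        β_i = α_i - α_i*, each in [-C, C], summing to ~0.
    bias_ : float
        Offset b of the dual expansion.
    dual_objective_ : float
        Value of the dual objective at the solution.
    """

    def __init__(self, C: float = 1.0, sigma: float = 1.0,
                 epsilon: float = 0.1, tol: float = 1e-8,
                 max_iter: int = -1):
        self.C = C
        self.sigma = sigma
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter

    def _validate_hp(self) -> SvrHyperparams:
        return SvrHyperparams(C=self.C, sigma=self.sigma, epsilon=self.epsilon)

    def fit(self, X: np.ndarray, y: np.ndarray,
            gram: np.ndarray | None = None) -> "GaussianSVR":
        """Fit on inputs X (n x d) and targets y (n,). ``gram`` optionally
        supplies a precomputed training Gram matrix for this sigma."""
        self._validate_hp()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValidationError("X and y disagree on the number of samples")
        if gram is None:
            gram = gaussian_gram(X, sigma=self.sigma)
        svr = _LibsvmSVR(kernel="precomputed", C=self.C, epsilon=self.epsilon,
                         tol=self.tol, max_iter=self.max_iter)
        with warnings.catch_warnings():
            # iteration-capped fits are reported via SolverError instead
            warnings.simplefilter("ignore", ConvergenceWarning)
            svr.fit(gram, y)
        if getattr(svr, "fit_status_", 0) != 0:
            raise SolverError(
                f"libsvm did not converge (C={self.C}, sigma={self.sigma}, "
                f"epsilon={self.epsilon}, n={y.size})")
        self.X_fit_ = X
        self.support_ = svr.support_.copy()
        self.support_inputs_ = X[svr.support_]
        self.dual_coefficients_ = svr.dual_coef_.ravel().copy()
        self.bias_ = float(svr.intercept_[0])
        self.n_features_in_ = X.shape[1]
        K_ss = gram[np.ix_(self.support_, self.support_)]
        beta = self.dual_coefficients_
        self.dual_objective_ = float(
            -0.5 * beta @ K_ss @ beta
            + y[self.support_] @ beta
            - self.epsilon * np.sum(np.abs(beta)))
        return self

    def _kernel_to_support(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return gaussian_gram(X, self.support_inputs_, self.sigma)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Dual-expansion prediction f(x) = Σ β_i K(x_i, x) + b."""
        check_is_fitted(self, "dual_coefficients_")
        return self._kernel_to_support(X) @ self.dual_coefficients_ + self.bias_

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Bias-free scores ω·φ(x) = f(x) - b (used by the MMC label step)."""
        check_is_fitted(self, "dual_coefficients_")
        return self._kernel_to_support(X) @ self.dual_coefficients_


class MultiOutputGaussianSVR(BaseEstimator, RegressorMixin):
    """Bank of GaussianSVRs, one per output column, sharing hyperparameters
    and the (precomputed) training Gram matrix.

    Used for the BSP -> TMP mapping: inputs are scaled lead vectors, each
    output column is the potential at one ventricular source node.
    """

    def __init__(self, C: float = 1.0, sigma: float = 1.0,
                 epsilon: float = 0.1, tol: float = 1e-6,
                 max_iter: int = -1):
        self.C = C
        self.sigma = sigma
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MultiOutputGaussianSVR":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValidationError("X and Y disagree on the number of samples")
        gram = gaussian_gram(X, sigma=self.sigma)
        models = []
        for j in range(Y.shape[1]):
            try:
                m = GaussianSVR(C=self.C, sigma=self.sigma,
                                epsilon=self.epsilon, tol=self.tol,
                                max_iter=self.max_iter)
                m.fit(X, Y[:, j], gram=gram)
            except Exception as exc:  # noqa: BLE001 - re-tagged with column id
                raise SolverError(f"SVR fit failed for output column {j}: {exc}"
                                  ) from exc
            models.append(m)
        self.models_ = models
        self.X_fit_ = X
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = Y.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict all outputs; shape (n_samples, n_outputs)."""
        check_is_fitted(self, "models_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        K = gaussian_gram(X, self.X_fit_, self.sigma)
        out = np.empty((X.shape[0], self.n_outputs_))
        for j, m in enumerate(self.models_):
            out[:, j] = K[:, m.support_] @ m.dual_coefficients_ + m.bias_
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def train_svr(X: np.ndarray, y: np.ndarray, hp: SvrHyperparams,
              tol: float = 1e-8) -> GaussianSVR:
    """Train a single-output SVR with the given hyperparameters."""
    return GaussianSVR(C=hp.C, sigma=hp.sigma, epsilon=hp.epsilon,
                       tol=tol).fit(X, y)


def predict_svr(model: GaussianSVR, x: np.ndarray) -> float | np.ndarray:
    """Evaluate the dual expansion at one point (or a batch of rows)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return float(model.predict(x[None, :])[0])
    return model.predict(x)


def train_multi_output(X: np.ndarray, Y: np.ndarray,
                       hp: SvrHyperparams, tol: float = 1e-6
                       ) -> MultiOutputGaussianSVR:
    """Train one SVR per column of Y with shared hyperparameters."""
    return MultiOutputGaussianSVR(C=hp.C, sigma=hp.sigma, epsilon=hp.epsilon,
                                  tol=tol).fit(X, Y)


def dual_objective(model: GaussianSVR) -> float:
    """Dual objective value of a fitted model (cached at fit time)."""
    check_is_fitted(model, "dual_objective_")
    return model.dual_objective_
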