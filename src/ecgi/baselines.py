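"""Linear regularized solvers for the inverse problem A·φm = φB.

Zero-order Tikhonov regularization, min ‖Ax − b‖² + λ²‖x‖², is solved in
SVD filter-factor form (the SVD of A is computed once and reused across
time instants and λ values — essential at condition numbers ~1e12), with
the regularization parameter chosen per instant by the L-curve corner
(maximum curvature of the log residual-norm vs log solution-norm curve).

LSQR is the Golub–Kahan-bidiagonalization iterative least-squares method
whose early termination acts as the regularizer; the iteration count is
chosen by the same L-curve logic over the iteration index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import lsqr as _scipy_lsqr

from .exceptions import ValidationError

__all__ = [
    "TikhonovConfig",
    "LsqrConfig",
    "TikhonovSolver",
    "tikhonov_solve",
    "select_lambda_lcurve",
    "default_lambda_grid",
    "lsqr_solve",
    "select_lsqr_iterations",
]


@dataclass(frozen=True)
class TikhonovConfig:
    """Tikhonov settings: a fixed λ, or L-curve selection over a grid."""

    lam: float | None = None
    selection: str = "l_curve"          # "fixed" | "l_curve"
    n_grid: int = 40
    lambda_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.selection not in ("fixed", "l_curve"):
            raise ValidationError("selection must be 'fixed' or 'l_curve'")
        if self.selection == "fixed" and (self.lam is None or self.lam < 0):
            raise ValidationError("fixed selection requires lam >= 0")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.size < 3 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
                raise ValidationError("lambda_grid must be positive, sorted, >= 3 points")


@dataclass(frozen=True)
class LsqrConfig:
    """LSQR settings: fixed iteration count or L-curve-selected count."""

    max_iter: int = 200
    stop_tol: float = 1e-10
    selection: str = "l_curve"          # "fixed_iter" | "l_curve"
    fixed_iter: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.stop_tol <= 0:
            raise ValidationError("stop_tol must be > 0")
        if self.selection not in ("fixed_iter", "l_curve"):
            raise ValidationError("selection must be 'fixed_iter' or 'l_curve'")


class TikhonovSolver:
    """Zero-order Tikhonov solver with a cached SVD of A.

    x(λ) = Σ_i  s_i (uᵢᵀb) / (s_i² + λ²) · v_i
    """

    def __init__(self, A: np.ndarray):
        A = np.atleast_2d(np.asarray(A, dtype=float))
        self.A = A
        self.U, self.s, Vt = np.linalg.svd(A, full_matrices=False)
        self.V = Vt.T

    def solve(self, b: np.ndarray, lam: float) -> np.ndarray:
        b = np.asarray(b, dtype=float).ravel()
        if b.size != self.A.shape[0]:
            raise ValidationError("b length must equal the number of rows of A")
        if lam < 0:
            raise ValidationError("lambda must be >= 0")
        beta = self.U.T @ b
        if lam == 0:
            tiny = self.s.max() * max(self.A.shape) * np.finfo(float).eps
            if self.s.min() <= tiny:
                raise ValidationError(
                    "lambda = 0 requires full column rank (rank-deficient A)")
            f = beta / self.s
        else:
            f = self.s * beta / (self.s ** 2 + lam ** 2)
        return self.V @ f

    def solve_matrix(self, B: np.ndarray, lam: float) -> np.ndarray:
        """Solve one λ for every column of B."""
        B = np.atleast_2d(np.asarray(B, dtype=float))
        beta = self.U.T @ B
        f = (self.s / (self.s ** 2 + lam ** 2))[:, None] * beta
        return self.V @ f

    def lcurve(self, b: np.ndarray, grid: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
        """Residual and solution norms along a λ grid (filter-factor form)."""
        b = np.asarray(b, dtype=float).ravel()
        beta = self.U.T @ b
        # component of b outside range(A) contributes a constant residual
        res_perp_sq = max(float(b @ b - beta @ beta), 0.0)
        rho = np.empty(grid.size)
        eta = np.empty(grid.size)
        for i, lam in enumerate(grid):
            f = self.s ** 2 / (self.s ** 2 + lam ** 2)
            eta[i] = np.linalg.norm((f / self.s) * beta)
            rho[i] = np.sqrt(np.sum(((1 - f) * beta) ** 2) + res_perp_sq)
        return rho, eta

    def lcurve_curvature(self, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """Analytic curvature of the (log ρ, log η) L-curve at each grid λ,
        from the SVD filter factors (exact derivatives, no finite
        differences)."""
        b = np.asarray(b, dtype=float).ravel()
        beta = self.U.T @ b
        res_perp_sq = max(float(b @ b - beta @ beta), 0.0)
        w = (beta / self.s) ** 2
        kappa = np.empty(grid.size)
        for i, lam in enumerate(grid):
            f = self.s ** 2 / (self.s ** 2 + lam ** 2)
            eta2 = float(np.sum(f ** 2 * w))
            rho2 = float(np.sum(((1 - f) * beta) ** 2)) + res_perp_sq
            if eta2 <= 0 or rho2 <= 0:
                kappa[i] = -np.inf
                continue
            # d(eta^2)/dlam and second derivative via df/dlam = -2 f(1-f)/lam
            S = float(np.sum(f ** 2 * (1 - f) * w))
            Sp = -(2.0 / lam) * float(np.sum((2 * f - 3 * f ** 2)
                                             * f * (1 - f) * w))
            deta2 = -(4.0 / lam) * S
            ddeta2 = (4.0 / lam ** 2) * S - (4.0 / lam) * Sp
            drho2 = -lam ** 2 * deta2
            ddrho2 = -2.0 * lam * deta2 - lam ** 2 * ddeta2
            xp = drho2 / (2 * rho2)
            yp = deta2 / (2 * eta2)
            xpp = (ddrho2 * rho2 - drho2 ** 2) / (2 * rho2 ** 2)
            ypp = (ddeta2 * eta2 - deta2 ** 2) / (2 * eta2 ** 2)
            denom = (xp ** 2 + yp ** 2) ** 1.5
            kappa[i] = (xp * ypp - yp * xpp) / denom if denom > 0 else -np.inf
        return kappa


def tikhonov_solve(A: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    """One-shot zero-order Tikhonov solve (use TikhonovSolver to amortize
    the SVD over many right-hand sides)."""
    return TikhonovSolver(A).solve(b, lam)


def default_lambda_grid(A_or_solver, n: int = 40) -> np.ndarray:
    """Log-spaced λ grid spanning the singular-value range of A, extended
    three decades below the smallest singular value so that clean
    (noise-free) data can select an essentially unregularized solution."""
    solver = (A_or_solver if isinstance(A_or_solver, TikhonovSolver)
              else TikhonovSolver(A_or_solver))
    smin = max(solver.s.min() * 1e-3, solver.s.max() * 1e-16)
    return np.geomspace(smin, solver.s.max(), n)


def _max_curvature_index(x: np.ndarray, y: np.ndarray) -> int:
    """Index of maximum (signed-convex) curvature of the discrete curve
    (x_i, y_i), by central finite differences in arc parameter."""
    t = np.arange(x.size, dtype=float)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx * dx + dy * dy) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / denom
    kappa[~np.isfinite(kappa)] = -np.inf
    return int(np.argmax(kappa))


def select_lambda_lcurve(A, b: np.ndarray,
                         lambda_grid: np.ndarray | None = None,
                         corner_min_curvature: float = 0.1) -> float:
    """L-curve corner: grid λ of maximum curvature of
    (log‖Ax−b‖, log‖x‖).

    A curve without a distinctly convex corner (max curvature below
    ``corner_min_curvature``, typical of noise-free consistent data whose
    L-curve is concave) selects the smallest grid λ — effectively no
    regularization. Degenerate (flat) curves fall back to the grid
    midpoint."""
    solver = A if isinstance(A, TikhonovSolver) else TikhonovSolver(A)
    grid = (np.asarray(lambda_grid, dtype=float) if lambda_grid is not None
            else default_lambda_grid(solver))
    if grid.size < 3:
        raise ValidationError("lambda grid needs at least 3 points")
    rho, eta = solver.lcurve(b, grid)
    if np.any(rho <= 0) or np.any(eta <= 0) or np.ptp(np.log(eta)) < 1e-12:
        return float(grid[grid.size // 2])
    kappa = solver.lcurve_curvature(b, grid)
    if not np.any(np.isfinite(kappa)):
        return float(grid[grid.size // 2])
    if np.nanmax(kappa) < corner_min_curvature:
        return float(grid[0])
    return float(grid[int(np.argmax(kappa))])


def lsqr_solve(A: np.ndarray, b: np.ndarray,
               config: LsqrConfig | None = None,
               n_iter: int | None = None) -> tuple[np.ndarray, int]:
    """LSQR iterate after a fixed number of Golub–Kahan steps.

    ``n_iter`` overrides the config's iteration count; with generous
    iterations on a well-conditioned system this converges to the
    minimum-norm least-squares solution. Returns (x, iterations_used)."""
    config = config or LsqrConfig()
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float).ravel()
    if b.size != A.shape[0]:
        raise ValidationError("b length must equal the number of rows of A")
    it = n_iter if n_iter is not None else (config.fixed_iter or config.max_iter)
    res = _scipy_lsqr(A, b, atol=config.stop_tol, btol=config.stop_tol,
                      conlim=0.0, iter_lim=it)
    return res[0], int(res[2])


def select_lsqr_iterations(A: np.ndarray, b: np.ndarray,
                           max_iter: int = 200) -> int:
    """Choose the LSQR stopping iteration by the L-curve corner over the
    iteration index (residual norm vs solution norm of the k-th iterate)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float).ravel()
    ks = np.unique(np.round(np.geomspace(1, max_iter, num=min(25, max_iter)))
                   .astype(int))
    rho = np.empty(ks.size)
    eta = np.empty(ks.size)
    for i, k in enumerate(ks):
        x, _ = lsqr_solve(A, b, LsqrConfig(max_iter=max_iter,
                                           selection="fixed_iter"), n_iter=int(k))
        rho[i] = np.linalg.norm(A @ x - b)
        eta[i] = np.linalg.norm(x)
    good = (rho > 0) & (eta > 0)
    if good.sum() < 3:
        return int(ks[-1])
    i = _max_curvature_index(np.log(rho[good]), np.log(eta[good]))
    return int(ks[good][i])
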