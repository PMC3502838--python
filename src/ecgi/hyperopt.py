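"""Two-stage GA + simplex hyperparameter search for the SVR models.

A real-coded genetic algorithm (tournament selection, blend crossover,
Gaussian mutation, elitism of one) explores the (C, σ, ε) space globally;
a Nelder–Mead simplex then refines the GA's best point locally. C and σ
are searched on a log10 scale. The fitness is k-fold cross-validated mean
squared error of the multi-output SVR, optionally probed on a seeded
subset of the output nodes to bound cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import KFold

from .exceptions import ValidationError
from .svr import MultiOutputGaussianSVR, SvrHyperparams

__all__ = [
    "SearchSpace",
    "SearchResult",
    "GaConfig",
    "cv_objective",
    "ga_search",
    "simplex_refine",
    "ga_simplex",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds for (C, sigma, epsilon); log10-scaled axes flagged."""

    c_bounds: tuple[float, float] = (1e-2, 1e4)
    sigma_bounds: tuple[float, float] = (1e-2, 1e2)
    epsilon_bounds: tuple[float, float] = (0.0, 0.5)
    log_c: bool = True
    log_sigma: bool = True
    log_epsilon: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi), is_log in (
            ("C", self.c_bounds, self.log_c),
            ("sigma", self.sigma_bounds, self.log_sigma),
            ("epsilon", self.epsilon_bounds, self.log_epsilon),
        ):
            if not lo < hi:
                raise ValidationError(f"{name} bounds must satisfy lower < upper")
            if is_log and lo <= 0:
                raise ValidationError(f"log-scaled {name} needs positive bounds")

    # -- transformed coordinates -------------------------------------

    def _axes(self):
        return ((self.c_bounds, self.log_c),
                (self.sigma_bounds, self.log_sigma),
                (self.epsilon_bounds, self.log_epsilon))

    def to_internal(self, hp: SvrHyperparams) -> np.ndarray:
        vals = (hp.C, hp.sigma, hp.epsilon)
        return np.array([np.log10(v) if lg else v
                         for v, ((lo, hi), lg) in zip(vals, self._axes())])

    def from_internal(self, z: np.ndarray) -> SvrHyperparams:
        z = self.clip(z)
        out = []
        for v, ((lo, hi), lg) in zip(z, self._axes()):
            out.append(10.0 ** v if lg else v)
        return SvrHyperparams(C=out[0], sigma=out[1], epsilon=out[2])

    def internal_bounds(self) -> np.ndarray:
        b = []
        for (lo, hi), lg in self._axes():
            b.append((np.log10(lo), np.log10(hi)) if lg else (lo, hi))
        return np.array(b)

    def clip(self, z: np.ndarray) -> np.ndarray:
        b = self.internal_bounds()
        return np.clip(z, b[:, 0], b[:, 1])

    def contains(self, hp: SvrHyperparams, rtol: float = 1e-9) -> bool:
        for v, ((lo, hi), _) in zip((hp.C, hp.sigma, hp.epsilon), self._axes()):
            if v < lo * (1 - rtol) - rtol or v > hi * (1 + rtol) + rtol:
                return False
        return True


@dataclass
class SearchResult:
    """Outcome of a search stage (or the full GA+simplex pipeline)."""

    best_params: SvrHyperparams
    best_score: float
    ga_history: list[float] = field(default_factory=list)
    simplex_trace: list[float] = field(default_factory=list)
    seed: int = 0
    n_evaluations: int = 0


@dataclass(frozen=True)
class GaConfig:
    """GA stage settings (population, generations, operators, budget)."""

    pop_size: int = 20
    generations: int = 15
    tournament_size: int = 2
    crossover_rate: float = 0.8
    blend_alpha: float = 0.5
    mutation_scale: float = 0.1     # fraction of each axis range
    mutation_rate: float = 0.3
    max_evaluations: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValidationError("pop_size must be >= 4")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")


def cv_objective(X: np.ndarray, Y: np.ndarray, params: SvrHyperparams,
                 folds: int = 5, seed: int = 0,
                 output_subsample: int | None = None,
                 svr_tol: float = 1e-4,
                 svr_max_iter: int = 50_000) -> float:
    """k-fold cross-validated MSE of the multi-output SVR, averaged over
    folds and output nodes.

    ``output_subsample`` probes a seeded subset of output columns (budget
    guard for wide target matrices); the split and subset are deterministic
    given ``seed``. ``svr_max_iter`` caps the SMO iterations per fit —
    hyperparameter corners that cannot be trained within the cap raise,
    which the search treats as worst fitness.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if n < folds:
        raise ValidationError(f"need at least {folds} samples for {folds} folds")
    cols = np.arange(Y.shape[1])
    if output_subsample is not None and output_subsample < cols.size:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(cols, size=output_subsample, replace=False))
    Ysub = Y[:, cols]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, va in kf.split(X):
        model = MultiOutputGaussianSVR(
            C=params.C, sigma=params.sigma, epsilon=params.epsilon,
            tol=svr_tol, max_iter=svr_max_iter).fit(X[tr], Ysub[tr])
        pred = model.predict(X[va])
        errs.append(float(np.mean((pred - Ysub[va]) ** 2)))
    return float(np.mean(errs))


class _Budget:
    """Evaluation counter with an optional cap; failures score +inf."""

    def __init__(self, objective, cap: int | None):
        self.objective = objective
        self.cap = cap
        self.count = 0
        self.exhausted = False

    def __call__(self, hp: SvrHyperparams) -> float:
        if self.cap is not None and self.count >= self.cap:
            self.exhausted = True
            return np.inf
        self.count += 1
        try:
            v = float(self.objective(hp))
        except Exception:   # noqa: BLE001 - failed points get worst fitness
            return np.inf
        return v if np.isfinite(v) else np.inf


def ga_search(objective, space: SearchSpace, pop_size: int = 20,
              generations: int = 15, seed: int = 0,
              ga_config: GaConfig | None = None) -> SearchResult:
    """Real-coded GA over the (transformed) search space.

    ``objective`` maps SvrHyperparams -> loss (lower is better). Returns
    the best-so-far point; ``ga_history`` records the best score after each
    generation (monotone by elitism).
    """
    cfg = ga_config or GaConfig(pop_size=pop_size, generations=generations)
    rng = np.random.default_rng(seed)
    bounds = space.internal_bounds()
    span = bounds[:, 1] - bounds[:, 0]
    budget = objective if isinstance(objective, _Budget) else _Budget(
        objective, cfg.max_evaluations)

    pop = rng.uniform(bounds[:, 0], bounds[:, 1], size=(cfg.pop_size, 3))
    fit = np.array([budget(space.from_internal(z)) for z in pop])
    history: list[float] = []

    def tournament() -> np.ndarray:
        idx = rng.integers(0, cfg.pop_size, size=cfg.tournament_size)
        return pop[idx[np.argmin(fit[idx])]]

    for _ in range(cfg.generations):
        elite_i = int(np.argmin(fit))
        nxt = [pop[elite_i].copy()]
        while len(nxt) < cfg.pop_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                # BLX-alpha blend crossover
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                d = hi - lo
                child = rng.uniform(lo - cfg.blend_alpha * d,
                                    hi + cfg.blend_alpha * d)
            else:
                child = p1.copy()
            mut = rng.random(3) < cfg.mutation_rate
            child = child + mut * rng.normal(0, cfg.mutation_scale * span)
            nxt.append(space.clip(child))
        pop = np.array(nxt)
        fit = np.concatenate([[fit[elite_i]],
                              [budget(space.from_internal(z))
                               for z in pop[1:]]])
        history.append(float(fit.min()))
        if budget.exhausted:
            break
    best_i = int(np.argmin(fit))
    return SearchResult(best_params=space.from_internal(pop[best_i]),
                        best_score=float(fit[best_i]), ga_history=history,
                        seed=seed, n_evaluations=budget.count)


def simplex_refine(objective, start: SvrHyperparams,
                   space: SearchSpace, max_iter: int = 60) -> SearchResult:
    """Nelder–Mead refinement from ``start`` with parameters clamped to the
    space; never returns a point worse than the start."""
    if not space.contains(start):
        raise ValidationError("start point outside the search space")
    budget = objective if isinstance(objective, _Budget) else _Budget(
        objective, None)
    trace: list[float] = []

    def f(z: np.ndarray) -> float:
        v = budget(space.from_internal(space.clip(z)))
        trace.append(v)
        return v

    z0 = space.to_internal(start)
    f0 = budget(start)
    res = minimize(f, z0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-4,
                            "fatol": 1e-8})
    if np.isfinite(res.fun) and res.fun < f0:
        best, score = space.from_internal(space.clip(res.x)), float(res.fun)
    else:
        best, score = start, float(f0)
    return SearchResult(best_params=best, best_score=score,
                        simplex_trace=trace, n_evaluations=budget.count)


def ga_simplex(X: np.ndarray, Y: np.ndarray,
               space: SearchSpace | None = None,
               ga_config: GaConfig | None = None,
               folds: int = 5, seed: int = 0,
               output_subsample: int | None = None,
               simplex_max_iter: int = 60,
               svr_tol: float = 1e-4,
               svr_max_iter: int = 50_000) -> SearchResult:
    """Full GA-then-simplex search of (C, σ, ε) against CV-MSE."""
    space = space or SearchSpace()
    cfg = ga_config or GaConfig()

    def obj(hp: SvrHyperparams) -> float:
        return cv_objective(X, Y, hp, folds=folds, seed=seed,
                            output_subsample=output_subsample,
                            svr_tol=svr_tol, svr_max_iter=svr_max_iter)

    budget = _Budget(obj, cfg.max_evaluations)
    ga = ga_search(budget, space, seed=seed, ga_config=cfg)
    sx = simplex_refine(budget, ga.best_params, space,
                        max_iter=simplex_max_iter)
    if sx.best_score <= ga.best_score:
        best, score = sx.best_params, sx.best_score
    else:
        best, score = ga.best_params, ga.best_score
    return SearchResult(best_params=best, best_score=score,
                        ga_history=ga.ga_history,
                        simplex_trace=sx.simplex_trace, seed=seed,
                        n_evaluations=budget.count)
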