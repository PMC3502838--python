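"""Maximum margin clustering (MMC) by alternating Laplacian-loss SVR.

MMC seeks the binary labeling y ∈ {±1}ⁿ of unlabeled samples that admits
the largest-margin separating hyperplane, subject to a class-balance bound
|Σ y_i| ≤ ℓ that forbids the degenerate one-class labeling. The non-convex
joint problem is attacked by alternating minimization:

  (a) with labels fixed, fit a support vector regressor with Laplacian
      (absolute-error) loss, i.e. an ε-SVR at ε = 0, to the ±1 labels;
  (b) with the kernel expansion ω fixed, choose the bias b and labels y
      minimizing Σ_i |ω·φ(x_i) + b − y_i| under the balance bound.

Step (b) has an exact combinatorial solution: the optimal labeling is
always monotone in the decision score, so it suffices to scan the n+1
threshold labelings in sorted-score order, refine b per labeling to its
closed-form optimum b = median(y_i − score_i), and keep the feasible
labeling of least objective.

The alternation monotonically decreases the full regularized objective
‖ω‖² + 2C Σ_i |ω·φ(x_i) + b − y_i| and is stopped when the label vector
repeats (fixed point or cycle) or an iteration cap is hit.  More than two
clusters are produced by recursive bisection, and test samples are routed
down the resulting tree by the sign of each split's decision function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import ValidationError
from .svr import GaussianSVR, gaussian_gram

__all__ = [
    "MmcConfig",
    "MmcSplit",
    "MmcTree",
    "init_labels",
    "optimal_bias_and_labels",
    "mmc_bisect",
    "mmc_cluster_k",
    "assign_cluster",
    "assign_clusters",
    "median_heuristic_sigma",
    "MaxMarginBisector",
    "MaxMarginClustering",
]


@dataclass(frozen=True)
class MmcConfig:
    """Configuration of one MMC run.

    ``sigma=None`` resolves to the median pairwise-distance heuristic and
    ``ell=None`` to ceil(0.2 n) (at most 40/60 class imbalance).
    """

    C: float = 1.0
    sigma: float | None = None
    ell: int | None = None
    max_iter: int = 50
    seed: int = 0
    init_method: str = "pca"
    svr_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be > 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.ell is not None and self.ell < 0:
            raise ValidationError("ell must be >= 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.init_method not in ("pca", "random"):
            raise ValidationError("init_method must be 'pca' or 'random'")


@dataclass
class MmcSplit:
    """One fitted binary max-margin split."""

    labels: np.ndarray              # ±1 per training sample
    model: GaussianSVR              # Laplacian-loss SVR holding ω in dual form
    bias: float                     # b chosen by the label step
    objective_trace: list[float]    # Σ|score_i + b − y_i| per iteration
    full_objective_trace: list[float]  # ‖ω‖² + 2C Σ|...| per iteration
    converged: bool
    n_iter: int
    ell: int
    sigma: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x) = ω·φ(x) + b with the label-step bias."""
        return self.model.decision_scores(X) + self.bias


@dataclass
class _TreeNode:
    sample_indices: np.ndarray
    split: MmcSplit | None = None
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    cluster_id: int | None = None


@dataclass
class MmcTree:
    """Recursive-bisection MMC tree; leaves are cluster ids 0..k-1."""

    root: _TreeNode
    n_clusters: int
    labels_: np.ndarray             # cluster id per training sample
    requested_k: int
    early_stopped: list[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        def d(node):
            if node.split is None:
                return 0
            return 1 + max(d(node.left), d(node.right))
        return d(self.root)


def median_heuristic_sigma(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance (a standard kernel-bandwidth
    heuristic); falls back to 1.0 on degenerate data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    return med if med > 0 else 1.0


def _resolve(X: np.ndarray, config: MmcConfig) -> tuple[float, int]:
    sigma = config.sigma if config.sigma is not None else median_heuristic_sigma(X)
    ell = config.ell if config.ell is not None else int(np.ceil(0.2 * X.shape[0]))
    return sigma, ell


# ---------------------------------------------------------------------------
# label initialization and the exact label step
# ---------------------------------------------------------------------------


def init_labels(X: np.ndarray, config: MmcConfig) -> np.ndarray:
    """Initial ±1 labeling satisfying the balance bound.

    ``pca``: sign of the centered scores along the first principal
    direction, with the smallest-|score| majority points flipped until
    |Σ y| ≤ ℓ. ``random``: seeded balanced random labeling.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples to initialize labels")
    _, ell = _resolve(X, config)
    if config.init_method == "random":
        rng = np.random.default_rng(config.seed)
        y = np.ones(n)
        y[rng.permutation(n)[: n // 2]] = -1
    else:
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[0]
        y = np.where(scores >= 0, 1.0, -1.0)
        # rebalance: flip majority points closest to the hyperplane
        order = np.argsort(np.abs(scores), kind="stable")
        for i in order:
            if abs(y.sum()) <= ell:
                break
            if y[i] == np.sign(y.sum()):
                y[i] = -y[i]
    if abs(y.sum()) > ell:
        raise ValidationError(
            f"cannot satisfy balance bound ell={ell} with n={n}")
    return y


def optimal_bias_and_labels(scores: np.ndarray, ell: int
                            ) -> tuple[float, np.ndarray, float]:
    """Exact minimizer of Σ|score_i + b − y_i| over b and balance-feasible
    labelings y ∈ {±1}ⁿ with |Σ y| ≤ ℓ.

    Scans the threshold labelings in sorted-score order (the optimum is
    always score-monotone: for fixed b the per-point flip cost is monotone
    in the score, so the balance-constrained optimum flips points nearest
    the threshold); for each feasible labeling b is set to its closed-form
    optimum, the median of y_i − score_i. Ties between equal-objective
    labelings resolve to the fewest-negatives one; scores that are all
    identical are handled by the same deterministic scan.
    """
    s = np.asarray(scores, dtype=float).ravel()
    n = s.size
    if n < 2:
        raise ValidationError("need at least 2 scores")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    order = np.argsort(s, kind="stable")
    best: tuple[float, float, np.ndarray] | None = None
    for p in range(n + 1):
        # lowest p scores -> -1, rest -> +1
        if abs(n - 2 * p) > ell:
            continue
        y = np.ones(n)
        y[order[:p]] = -1.0
        b = float(np.median(y - s))
        obj = float(np.sum(np.abs(s + b - y)))
        if best is None or obj < best[0]:
            best = (obj, b, y)
    if best is None:
        raise ValidationError(
            f"no labeling satisfies |sum(y)| <= {ell} for n={n}")
    obj, b, y = best
    return b, y, obj


# ---------------------------------------------------------------------------
# alternating bisection
# ---------------------------------------------------------------------------


def mmc_bisect(X: np.ndarray, config: MmcConfig | None = None) -> MmcSplit:
    """One binary max-margin split by the alternating SVR procedure."""
    config = config or MmcConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples to bisect")
    sigma, ell = _resolve(X, config)
    gram = gaussian_gram(X, sigma=sigma)

    y = init_labels(X, config)
    seen = {y.tobytes()}
    trace7: list[float] = []
    trace_full: list[float] = []
    converged = False
    model = None
    bias = 0.0
    it = 0
    for it in range(1, config.max_iter + 1):
        model = GaussianSVR(C=config.C, sigma=sigma, epsilon=0.0,
                            tol=config.svr_tol).fit(X, y, gram=gram)
        scores = gram[:, model.support_] @ model.dual_coefficients_
        bias, y_new, obj7 = optimal_bias_and_labels(scores, ell)
        beta = model.dual_coefficients_
        omega_sq = float(
            beta @ gram[np.ix_(model.support_, model.support_)] @ beta)
        trace7.append(obj7)
        trace_full.append(omega_sq + 2.0 * config.C * obj7)
        if np.array_equal(y_new, y):
            y = y_new
            converged = True
            break
        key = y_new.tobytes()
        if key in seen:          # cycle: stop without claiming convergence
            y = y_new
            break
        seen.add(key)
        y = y_new
    return MmcSplit(labels=y, model=model, bias=bias,
                    objective_trace=trace7, full_objective_trace=trace_full,
                    converged=converged, n_iter=it, ell=ell, sigma=sigma)


def mmc_cluster_k(X: np.ndarray, k: int,
                  config: MmcConfig | None = None) -> MmcTree:
    """Partition into k clusters (k a power of 2) by recursive bisection.

    A branch whose side holds fewer than 2 samples stops early and is
    recorded in ``tree.early_stopped``; the realized number of leaves may
    then be below k.
    """
    config = config or MmcConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if k < 1 or (k & (k - 1)) != 0:
        raise ValidationError("k must be a positive power of 2")
    if n < k:
        raise ValidationError(f"need at least k={k} samples, got {n}")

    early: list[str] = []
    leaf_counter = [0]
    labels = np.full(n, -1, dtype=int)

    def build(indices: np.ndarray, want: int, node_seed: int) -> _TreeNode:
        node = _TreeNode(sample_indices=indices)
        if want <= 1 or indices.size < 2:
            if want > 1:
                early.append(
                    f"branch with {indices.size} samples stopped before "
                    f"reaching {want} leaves")
            node.cluster_id = leaf_counter[0]
            labels[indices] = node.cluster_id
            leaf_counter[0] += 1
            return node
        sub_cfg = replace(config, seed=node_seed)
        split = mmc_bisect(X[indices], sub_cfg)
        neg = indices[split.labels < 0]
        pos = indices[split.labels > 0]
        if neg.size == 0 or pos.size == 0:
            # balance bound should prevent this; guard for tiny n
            early.append(f"degenerate one-sided split at {indices.size} samples")
            node.cluster_id = leaf_counter[0]
            labels[indices] = node.cluster_id
            leaf_counter[0] += 1
            return node
        node.split = split
        node.left = build(neg, want // 2, node_seed * 2 + 1)
        node.right = build(pos, want // 2, node_seed * 2 + 2)
        return node

    root = build(np.arange(n), k, config.seed)
    return MmcTree(root=root, n_clusters=leaf_counter[0], labels_=labels,
                   requested_k=k, early_stopped=early)


def assign_clusters(tree: MmcTree, X: np.ndarray) -> np.ndarray:
    """Route each row of X down the tree by the sign of each split's
    decision function (f(x) = 0 routes to the positive side)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(X.shape[0], dtype=int)

    def route(node: _TreeNode, idx: np.ndarray) -> None:
        if node.cluster_id is not None:
            out[idx] = node.cluster_id
            return
        f = node.split.decision_function(X[idx])
        neg = f < 0
        if neg.any():
            route(node.left, idx[neg])
        if (~neg).any():
            route(node.right, idx[~neg])

    route(tree.root, np.arange(X.shape[0]))
    return out


def assign_cluster(tree: MmcTree, x: np.ndarray) -> int:
    """Cluster id of one sample."""
    return int(assign_clusters(tree, np.asarray(x)[None, :])[0])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class MaxMarginBisector(BaseEstimator, ClusterMixin):
    """Binary maximum margin clustering estimator.

    Attributes after fit: ``labels_`` (±1), ``split_`` (MmcSplit with the
    dual-form decision model and objective traces), ``converged_``.
    """

    def __init__(self, C: float = 1.0, sigma: float | None = None,
                 ell: int | None = None, max_iter: int = 50,
                 init_method: str = "pca", random_state: int = 0):
        self.C = C
        self.sigma = sigma
        self.ell = ell
        self.max_iter = max_iter
        self.init_method = init_method
        self.random_state = random_state

    def _config(self) -> MmcConfig:
        return MmcConfig(C=self.C, sigma=self.sigma, ell=self.ell,
                         max_iter=self.max_iter, seed=self.random_state,
                         init_method=self.init_method)

    def fit(self, X: np.ndarray, y=None) -> "MaxMarginBisector":
        self.split_ = mmc_bisect(X, self._config())
        self.labels_ = self.split_.labels.astype(int)
        self.converged_ = self.split_.converged
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.split_.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_function(X)
        return np.where(f < 0, -1, 1)


class MaxMarginClustering(BaseEstimator, ClusterMixin):
    """k-cluster MMC by recursive bisection (k a power of 2).

    ``fit`` exposes ``labels_`` (cluster id per sample) and ``tree_``;
    ``predict`` routes new samples down the fitted tree.
    """

    def __init__(self, n_clusters: int = 4, C: float = 1.0,
                 sigma: float | None = None, ell: int | None = None,
                 max_iter: int = 50, init_method: str = "pca",
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.C = C
        self.sigma = sigma
        self.ell = ell
        self.max_iter = max_iter
        self.init_method = init_method
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "MaxMarginClustering":
        cfg = MmcConfig(C=self.C, sigma=self.sigma, ell=self.ell,
                        max_iter=self.max_iter, seed=self.random_state,
                        init_method=self.init_method)
        self.tree_ = mmc_cluster_k(X, self.n_clusters, cfg)
        self.labels_ = self.tree_.labels_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return assign_clusters(self.tree_, X)
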