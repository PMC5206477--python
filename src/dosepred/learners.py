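"""From-scratch regression learners: a CART-style tree and ε-insensitive SVR.

Regression tree
---------------
Recursive binary partitioning: every node considers all (feature, split
point) pairs, where candidate split points are midpoints between consecutive
distinct sorted values, and picks the pair minimizing the summed within-child
sum of squared errors.  A leaf predicts the mean response of the training
samples routed to it.  A split is accepted only if it reduces SSE by at
least ``cp`` times the root sum of squares (CART complexity gate), both
children hold at least ``min_node_size`` samples, and the depth bound is
respected.  Tie-breaks are pinned: smallest feature index, then smallest
split point; the boundary value ``x_j == s`` routes left.

ε-insensitive SVR
-----------------
f(x) = <w, x> + b (or its kernel expansion) chosen to minimize
``1/2 ||w||^2 + (C/N) * sum_i L_eps(y_i, f(x_i))`` where the ε-insensitive
loss is zero inside a tube of half-width ε and linear outside.  The box
bound of the dual is therefore C/N — the loss term carries an explicit 1/N —
so C grids are relative to this scaling.  The convex dual is solved by an
SMO working-set scheme with maximal-violating-pair selection; the bias b is
recovered from the KKT conditions on free (unbounded) support vectors, with
a feasible-interval midpoint fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "TreeNode",
    "RTConfig",
    "find_best_split",
    "rt_fit",
    "rt_predict",
    "tree_to_dict",
    "tree_from_dict",
    "RegressionTree",
    "SVRConfig",
    "SVRModel",
    "kernel_matrix",
    "svr_fit",
    "svr_predict",
    "svr_to_dict",
    "svr_from_dict",
    "EpsilonSVR",
]


# --------------------------------------------------------------------------
# regression tree
# --------------------------------------------------------------------------

@dataclass
class RTConfig:
    """Tree growth controls: node size floor, complexity gate, depth cap."""

    min_node_size: int = 5
    cp: float = 0.01
    max_depth: int = 10

    def __post_init__(self) -> None:
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not 0.0 <= self.cp <= 1.0:
            raise ValueError("cp must lie in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class TreeNode:
    value: float                      # leaf constant c_m = mean(y in region)
    n_node: int
    sse_node: float
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def find_best_split(
    X: np.ndarray, y: np.ndarray, min_node_size: int = 2
) -> tuple[int, float, float] | None:
    """Exact minimizer of summed child SSE over all features and midpoints.

    Returns ``(j, s, sse_left + sse_right)`` or ``None`` when no admissible
    split exists.  Ties break toward the smallest feature index, then the
    smallest split point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    # near-ties (within floating-point noise of the running SSE formula) are
    # resolved toward smaller j / smaller s, matching the documented tie-break
    tol = 1e-9 * max(1.0, float(y @ y))
    best: tuple[float, int, float] | None = None
    for j in range(p):
        xj = X[:, j]
        order = np.argsort(xj, kind="mergesort")
        xs = xj[order]
        ys = y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys * ys)
        total, total_sq = csum[-1], csq[-1]
        k = np.arange(1, n)  # left child sizes
        valid = (xs[1:] != xs[:-1]) & (k >= min_node_size) & ((n - k) >= min_node_size)
        if not valid.any():
            continue
        left = csq[:-1] - csum[:-1] ** 2 / k
        right = (total_sq - csq[:-1]) - (total - csum[:-1]) ** 2 / (n - k)
        sse = np.maximum(left, 0.0) + np.maximum(right, 0.0)
        sse[~valid] = np.inf
        m = float(np.min(sse))
        i = int(np.argmax(sse <= m + tol))  # smallest split point among ties
        if best is None or sse[i] < best[0] - tol:
            s = 0.5 * (xs[i] + xs[i + 1])
            best = (float(sse[i]), j, float(s))
    if best is None:
        return None
    return best[1], best[2], best[0]


def _node_stats(y: np.ndarray) -> tuple[float, float]:
    mean = float(y.mean())
    return mean, float(np.sum((y - mean) ** 2))


def rt_fit(X: np.ndarray, y: np.ndarray, cfg: RTConfig | None = None) -> TreeNode:
    """Grow a regression tree by greedy recursive binary splitting."""
    cfg = cfg or RTConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) == 0:
        raise ValueError("X must be (n, p) with matching non-empty y")
    _, sst_root = _node_stats(y)
    min_gain = cfg.cp * sst_root

    def grow(Xn: np.ndarray, yn: np.ndarray, depth: int) -> TreeNode:
        mean, sse = _node_stats(yn)
        node = TreeNode(value=mean, n_node=len(yn), sse_node=sse)
        if depth >= cfg.max_depth or len(yn) < 2 * cfg.min_node_size:
            return node
        found = find_best_split(Xn, yn, cfg.min_node_size)
        if found is None:
            return node
        j, s, child_sse = found
        gain = sse - child_sse
        if gain <= 0.0 or gain < min_gain:
            return node
        mask = Xn[:, j] <= s
        # midpoint degeneracy guard: both children must stay admissible
        if mask.sum() < cfg.min_node_size or (~mask).sum() < cfg.min_node_size:
            return node
        node.feature, node.threshold = j, s
        node.left = grow(Xn[mask], yn[mask], depth + 1)
        node.right = grow(Xn[~mask], yn[~mask], depth + 1)
        return node

    return grow(X, y, 0)


def rt_predict(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Route each row down the tree (``x_j <= s`` goes left), return leaf means."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0], dtype=float)
    stack = [(tree, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            out[idx] = node.value
        else:
            mask = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
    return out


def tree_to_dict(node: TreeNode) -> dict:
    d = {"value": node.value, "n_node": node.n_node, "sse_node": node.sse_node}
    if not node.is_leaf:
        d.update(
            feature=node.feature,
            threshold=node.threshold,
            left=tree_to_dict(node.left),
            right=tree_to_dict(node.right),
        )
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(value=d["value"], n_node=d["n_node"], sse_node=d["sse_node"])
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = d["threshold"]
        node.left = tree_from_dict(d["left"])
        node.right = tree_from_dict(d["right"])
    return node


class RegressionTree:
    """Estimator-style wrapper around :func:`rt_fit` / :func:`rt_predict`."""

    def __init__(self, config: RTConfig | None = None):
        self.config = config or RTConfig()
        self.tree_: TreeNode | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionTree":
        self.tree_ = rt_fit(X, y, self.config)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.tree_ is None:
            raise RuntimeError("tree is not fitted")
        return rt_predict(self.tree_, X)

    def clone(self) -> "RegressionTree":
        return RegressionTree(self.config)


# --------------------------------------------------------------------------
# epsilon-insensitive support vector regression
# --------------------------------------------------------------------------

@dataclass
class SVRConfig:
    """Cost C, tube half-width ε and kernel for ε-SVR.

    ``degree``, ``gamma`` and ``coef0`` only apply to the polynomial kernel
    ``(gamma * <x, x'> + coef0) ** degree``.
    """

    C: float = 1.0
    epsilon: float = 0.1
    kernel: str = "linear"
    degree: int = 3
    gamma: float = 1.0
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.kernel not in ("linear", "polynomial"):
            raise ValueError(f"unsupported kernel '{self.kernel}'")
        if self.kernel == "polynomial":
            if self.degree < 2:
                raise ValueError("polynomial degree must be >= 2")
            if self.gamma <= 0:
                raise ValueError("gamma must be positive")


def kernel_matrix(cfg: SVRConfig, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    G = A @ B.T
    if cfg.kernel == "linear":
        return G
    return (cfg.gamma * G + cfg.coef0) ** cfg.degree


@dataclass
class SVRModel:
    """Fitted ε-SVR: dual expansion over support rows plus bias."""

    dual_coefs: np.ndarray            # beta_i = alpha_i - alpha_i* (support only)
    support_X: np.ndarray
    b: float
    config: SVRConfig
    n_train: int
    objective: float                  # dual objective at convergence (min form)
    w: np.ndarray | None = None       # explicit weights, linear kernel only
    kkt_violation: float = 0.0


def _smo_solve(
    K: np.ndarray,
    y: np.ndarray,
    box: float,
    eps: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """SMO with maximal-violating-pair selection on the 2n-variable dual.

    Variables are (alpha, alpha*) each in [0, box]; signs z = (+1, -1);
    objective (minimized) is
    ``1/2 beta' K beta + eps * sum(alpha + alpha*) - y' beta`` with
    ``beta = alpha - alpha*`` and the balance constraint sum(beta) = 0.
    Returns (alpha, alpha_star, final KKT violation m - M).
    """
    n = len(y)
    alpha = np.zeros(n)
    alpha_star = np.zeros(n)
    Kb = np.zeros(n)  # K @ beta, maintained incrementally

    violation = np.inf
    for _ in range(max_iter):
        # gradients of the two blocks
        g_plus = Kb + eps - y        # d f / d alpha_i
        g_minus = -Kb + eps + y      # d f / d alpha_i*
        # -z_i G_i scores: plus block -> -g_plus, minus block -> +g_minus
        up_plus = np.where(alpha < box, -g_plus, -np.inf)
        up_minus = np.where(alpha_star > 0, g_minus, -np.inf)
        low_plus = np.where(alpha > 0, -g_plus, np.inf)
        low_minus = np.where(alpha_star < box, g_minus, np.inf)

        i_plus, i_minus = int(np.argmax(up_plus)), int(np.argmax(up_minus))
        if up_plus[i_plus] >= up_minus[i_minus]:
            i, zi = i_plus, 1
            m_val = up_plus[i_plus]
        else:
            i, zi = i_minus, -1
            m_val = up_minus[i_minus]
        j_plus, j_minus = int(np.argmin(low_plus)), int(np.argmin(low_minus))
        if low_plus[j_plus] <= low_minus[j_minus]:
            j, zj = j_plus, 1
            M_val = low_plus[j_plus]
        else:
            j, zj = j_minus, -1
            M_val = low_minus[j_minus]

        violation = m_val - M_val
        if not np.isfinite(violation) or violation < tol:
            break

        # direction: a_i moves by zi*t, a_j by -zj*t; beta_i += t, beta_j -= t
        gi = g_plus[i] if zi == 1 else g_minus[i]
        gj = g_plus[j] if zj == 1 else g_minus[j]
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        deriv = zi * gi - zj * gj
        if eta > 1e-12:
            t = -deriv / eta
        else:
            t = -np.sign(deriv) * box  # flat direction: step to a bound
        # box clipping for both coordinates
        if zi == 1:
            lo_i, hi_i = -alpha[i], box - alpha[i]          # a_i + t in [0,box]
        else:
            lo_i, hi_i = alpha_star[i] - box, alpha_star[i]  # a_i - t in [0,box]
        if zj == 1:
            lo_j, hi_j = alpha[j] - box, alpha[j]
        else:
            lo_j, hi_j = -alpha_star[j], box - alpha_star[j]
        t = min(max(t, lo_i, lo_j), hi_i, hi_j)
        if t == 0.0:
            break
        if zi == 1:
            alpha[i] += t
        else:
            alpha_star[i] -= t
        if zj == 1:
            alpha[j] -= t
        else:
            alpha_star[j] += t
        Kb += t * (K[:, i] - K[:, j])

    # enforce exact per-sample complementarity (never both active);
    # subtracting the pairwise minimum preserves beta and dual feasibility
    both = np.minimum(alpha, alpha_star)
    alpha -= both
    alpha_star -= both
    return alpha, alpha_star, float(max(violation, 0.0))


def svr_fit(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SVRConfig | None = None,
    tol: float = 1e-8,
    max_iter: int = 200_000,
) -> SVRModel:
    """Solve the ε-SVR dual; box bound is C/N per the 1/N loss scaling."""
    cfg = cfg or SVRConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    K = kernel_matrix(cfg, X, X)
    if np.any(np.diag(K) < -1e-10):
        raise ValueError("kernel matrix is not positive semidefinite")
    box = cfg.C / n
    alpha, alpha_star, viol = _smo_solve(K, y, box, cfg.epsilon, tol, max_iter)
    beta = alpha - alpha_star
    Kb = K @ beta
    e = y - Kb

    # bias from KKT: free SVs satisfy e_i - b = +eps (alpha) or -eps (alpha*)
    bound_tol = 1e-10 * max(box, 1.0)
    free_a = (alpha > bound_tol) & (alpha < box - bound_tol)
    free_s = (alpha_star > bound_tol) & (alpha_star < box - bound_tol)
    biases = np.concatenate([e[free_a] - cfg.epsilon, e[free_s] + cfg.epsilon])
    if biases.size:
        b = float(biases.mean())
    else:
        lo = -np.inf
        hi = np.inf
        at_zero_a = alpha <= bound_tol
        at_box_a = alpha >= box - bound_tol
        at_zero_s = alpha_star <= bound_tol
        at_box_s = alpha_star >= box - bound_tol
        if at_zero_a.any():
            lo = max(lo, np.max(e[at_zero_a] - cfg.epsilon))
        if at_box_s.any():
            lo = max(lo, np.max(e[at_box_s] + cfg.epsilon))
        if at_box_a.any():
            hi = min(hi, np.min(e[at_box_a] - cfg.epsilon))
        if at_zero_s.any():
            hi = min(hi, np.min(e[at_zero_s] + cfg.epsilon))
        if np.isfinite(lo) and np.isfinite(hi):
            b = float(0.5 * (lo + hi))
        elif np.isfinite(lo):
            b = float(lo)
        elif np.isfinite(hi):
            b = float(hi)
        else:
            b = float(y.mean())

    objective = float(
        0.5 * beta @ Kb + cfg.epsilon * (alpha.sum() + alpha_star.sum()) - y @ beta
    )
    support = np.abs(beta) > bound_tol
    w = X.T @ beta if cfg.kernel == "linear" else None
    return SVRModel(
        dual_coefs=beta[support],
        support_X=X[support].copy(),
        b=b,
        config=cfg,
        n_train=n,
        objective=objective,
        w=w,
        kkt_violation=viol,
    )


def svr_predict(model: SVRModel, X: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = sum_i beta_i K(x_i, x) + b."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d_train = (
        model.support_X.shape[1]
        if model.support_X.size
        else (len(model.w) if model.w is not None else X.shape[1])
    )
    if X.shape[1] != d_train:
        raise ValueError(
            f"feature dimension {X.shape[1]} != training dimension {d_train}"
        )
    if model.support_X.size == 0:
        return np.full(X.shape[0], model.b)
    K = kernel_matrix(model.config, X, model.support_X)
    return K @ model.dual_coefs + model.b


def svr_to_dict(model: SVRModel) -> dict:
    return {
        "dual_coefs": model.dual_coefs.tolist(),
        "support_X": model.support_X.tolist(),
        "b": model.b,
        "n_train": model.n_train,
        "objective": model.objective,
        "config": vars(model.config).copy(),
    }


def svr_from_dict(d: dict) -> SVRModel:
    cfg = SVRConfig(**d["config"])
    support = np.asarray(d["support_X"], dtype=float)
    if support.size == 0:
        support = support.reshape(0, 0)
    model = SVRModel(
        dual_coefs=np.asarray(d["dual_coefs"], dtype=float),
        support_X=support,
        b=float(d["b"]),
        config=cfg,
        n_train=int(d["n_train"]),
        objective=float(d["objective"]),
    )
    if cfg.kernel == "linear" and model.support_X.size:
        model.w = model.support_X.T @ model.dual_coefs
    return model


class EpsilonSVR:
    """Estimator-style wrapper around :func:`svr_fit` / :func:`svr_predict`."""

    def __init__(self, config: SVRConfig | None = None):
        self.config = config or SVRConfig()
        self.model_: SVRModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EpsilonSVR":
        self.model_ = svr_fit(X, y, self.config)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("SVR is not fitted")
        return svr_predict(self.model_, X)

    def clone(self) -> "EpsilonSVR":
        return EpsilonSVR(self.config)
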