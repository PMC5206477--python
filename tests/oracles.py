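"""Independent brute-force / generic-solver oracles used by the tests.

Everything here is deliberately naive and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_best_split(X, y, min_node_size=2):
    """Exhaustive scan over every feature and midpoint; first-best wins."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    tol = 1e-9 * max(1.0, float(y @ y))  # same near-tie rule as the package
    best = None  # (sse, j, s)
    for j in range(p):
        values = np.sort(np.unique(X[:, j]))
        for a, b in zip(values[:-1], values[1:]):
            s = 0.5 * (a + b)
            left = X[:, j] <= s
            nl, nr = left.sum(), n - left.sum()
            if nl < min_node_size or nr < min_node_size:
                continue
            sse = (
                np.sum((y[left] - y[left].mean()) ** 2)
                + np.sum((y[~left] - y[~left].mean()) ** 2)
            )
            if best is None or sse < best[0] - tol:
                best = (sse, j, s)
    return best  # None or (sse, j, s)


def brute_force_greedy_tree_sse(X, y, min_node_size, max_depth):
    """Training SSE of the greedy tree grown by the naive recursion."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def grow(Xn, yn, depth):
        sse_leaf = float(np.sum((yn - yn.mean()) ** 2))
        if depth >= max_depth or len(yn) < 2 * min_node_size:
            return sse_leaf
        found = brute_force_best_split(Xn, yn, min_node_size)
        if found is None or not found[0] < sse_leaf:
            return sse_leaf
        _, j, s = found
        mask = Xn[:, j] <= s
        return grow(Xn[mask], yn[mask], depth + 1) + grow(
            Xn[~mask], yn[~mask], depth + 1
        )

    return grow(X, y, 0)


def qp_svr_dual(K, y, box, eps):
    """Generic convex-solver (SLSQP) solution of the ε-SVR dual.

    Variables are (alpha, alpha*) stacked; minimizes
    ``1/2 (a-a*)' K (a-a*) + eps * sum(a+a*) - y'(a-a*)`` under the box and
    balance constraints.  Returns (objective, beta).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)

    def split(v):
        return v[:n], v[n:]

    def fun(v):
        a, s = split(v)
        beta = a - s
        return 0.5 * beta @ K @ beta + eps * v.sum() - y @ beta

    def grad(v):
        a, s = split(v)
        Kb = K @ (a - s)
        return np.concatenate([Kb + eps - y, -Kb + eps + y])

    cons = {
        "type": "eq",
        "fun": lambda v: np.sum(v[:n]) - np.sum(v[n:]),
        "jac": lambda v: np.concatenate([np.ones(n), -np.ones(n)]),
    }
    res = minimize(
        fun,
        x0=np.zeros(2 * n),
        jac=grad,
        bounds=[(0.0, box)] * (2 * n),
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a, s = split(res.x)
    return float(fun(res.x)), a - s


def eps_insensitive_loss(y, f, eps):
    return float(np.sum(np.maximum(np.abs(y - f) - eps, 0.0)))
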