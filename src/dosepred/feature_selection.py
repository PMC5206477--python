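"""Iterative sure independence screening with lasso refinement.

For p >> n expression matrices, ordinary least squares cannot be fit and
marginal screening alone can miss genes whose effect is only visible jointly
with others.  The procedure here alternates the two classical moves:

1. *Screen*: rank genes by the magnitude of their Pearson correlation with a
   target (the dose on the first pass, an OLS residual afterwards) and keep
   the top ``d`` (default ``floor(n / ln n)``).
2. *Select*: run a cross-validated lasso on the screened union and keep the
   genes with nonzero coefficients.

Iterating on residuals lets marginally weak but jointly relevant genes enter
on later passes.  A post-filter then prunes the selected set by
multicollinearity (drop the largest variance-inflation factor while any
exceeds the threshold) and by OLS coefficient significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ISISConfig",
    "SelectionResult",
    "PostFilterConfig",
    "LassoResult",
    "marginal_screen",
    "lasso_fit",
    "isis_select",
    "post_filter",
    "ols_pvalues",
    "variance_inflation",
]


@dataclass
class ISISConfig:
    """Controls for iterative screening: screen size d, iterations, lasso CV."""

    d: int | None = None          # None => floor(n / ln n), clipped to [1, p]
    max_iter: int = 5
    lambda_grid: np.ndarray | None = None   # None => 30-point log path
    n_lambda: int = 30
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 10
    lambda_rule: str = "1se"     # "1se" (sparser, default) or "min"
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")
        if self.lambda_grid is not None:
            lg = np.asarray(self.lambda_grid, dtype=float)
            if np.any(lg <= 0) or np.any(np.diff(lg) >= 0):
                raise ValueError("lambda_grid must be positive and decreasing")
            self.lambda_grid = lg

    def resolve_d(self, n: int, p: int) -> int:
        if self.d is not None:
            if not 1 <= self.d <= p:
                raise ValueError("d must lie in [1, p]")
            return self.d
        return max(1, min(p, int(math.floor(n / math.log(n)))))


@dataclass
class SelectionResult:
    """Outcome of iterative screening: the gene set and a per-iteration trace."""

    selected: list[str]
    selected_idx: list[int]
    trace: list[dict]
    marginal_stats: np.ndarray


@dataclass
class PostFilterConfig:
    vif_threshold: float = 10.0
    p_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")


@dataclass
class LassoResult:
    active: list[int]             # column indices into X_sub
    coef: np.ndarray              # coefficients on the standardized scale
    lam: float
    lambda_grid: np.ndarray
    cv_mse: np.ndarray


def marginal_screen(
    X: np.ndarray, r: np.ndarray, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rank genes by |Pearson correlation| with the target, keep the top d.

    Returns ``(ranked_idx, stats)`` where ``ranked_idx`` holds the d columns
    with the largest absolute correlation in decreasing order and ``stats``
    the full length-p vector of |corr|.  Zero-variance columns score 0; the
    statistic is invariant to affine rescaling of any column.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    n, p = X.shape
    if d > p:
        raise ValueError("d cannot exceed the number of genes")
    rc = r - r.mean()
    r_norm = np.sqrt(rc @ rc)
    if r_norm == 0.0:
        raise ValueError("degenerate screening target: target is constant")
    Xc = X - X.mean(axis=0)
    col_norm = np.sqrt(np.sum(Xc * Xc, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(Xc.T @ rc) / (col_norm * r_norm)
    stat[col_norm == 0.0] = 0.0
    stat = np.clip(stat, 0.0, 1.0)
    ranked = np.argsort(-stat, kind="mergesort")[:d]
    return ranked, stat


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd


def _cd_lasso(
    G: np.ndarray,
    c: np.ndarray,
    lam: float,
    beta: np.ndarray,
    tol: float,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Cyclic coordinate descent for (1/2n)||r - Xb||^2 + lam*||b||_1.

    Works on sufficient statistics of the standardized design:
    ``G = X'X / n`` (unit diagonal) and ``c = X'r / n``, so each coordinate
    update is O(p) regardless of n.
    """
    p = len(c)
    q = G @ beta            # G beta, maintained incrementally

    def sweep(indices) -> float:
        nonlocal q
        delta = 0.0
        for j in indices:
            bj = beta[j]
            rho = c[j] - q[j] + G[j, j] * bj
            bn = math.copysign(max(abs(rho) - lam, 0.0), rho)
            if bn != bj:
                q += (bn - bj) * G[:, j]
                delta = max(delta, abs(bn - bj))
                beta[j] = bn
        return delta

    all_idx = range(p)
    for _ in range(max_sweeps):
        # full pass establishes/extends the active set (KKT check for zeros)
        if sweep(all_idx) < tol:
            break
        # then iterate the nonzero set to convergence (glmnet-style)
        for _ in range(max_sweeps):
            active = np.nonzero(beta)[0]
            if active.size == 0 or sweep(active) < tol:
                break
    return beta


def _lambda_grid(Xs: np.ndarray, rc: np.ndarray, cfg: ISISConfig) -> np.ndarray:
    if cfg.lambda_grid is not None:
        return cfg.lambda_grid
    n = len(rc)
    lam_max = np.max(np.abs(Xs.T @ rc)) / n
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def lasso_fit(
    X_sub: np.ndarray,
    r: np.ndarray,
    cfg: ISISConfig | None = None,
    seed: int = 0,
) -> LassoResult:
    """Coordinate-descent lasso path with K-fold CV choice of λ.

    Columns are standardized to unit variance internally; the objective is
    ``(1/2n)||r - Xb||^2 + λ||b||_1`` so that ``λ_max = max_j |x_j'r| / n``
    on the standardized design empties the active set.  By default λ follows
    the one-standard-error rule (the largest λ whose CV error is within one
    SE of the minimum — the conventional sparser choice); ``lambda_rule=
    "min"`` picks the plain CV minimizer.  Ties break toward the larger
    (sparser) λ.
    """
    cfg = cfg or ISISConfig()
    X_sub = np.atleast_2d(np.asarray(X_sub, dtype=float))
    r = np.asarray(r, dtype=float)
    n, p = X_sub.shape
    if n < cfg.cv_folds:
        raise ValueError(
            f"fewer samples ({n}) than CV folds ({cfg.cv_folds})"
        )
    Xs, _, sd = _standardize(X_sub)
    rc = r - r.mean()
    grid = _lambda_grid(Xs, rc, cfg)

    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(n) % cfg.cv_folds)
    fold_mse = np.zeros((cfg.cv_folds, len(grid)))
    for f in range(cfg.cv_folds):
        val = fold_of == f
        Xt, rt = Xs[~val], rc[~val]
        Xv, rv = Xs[val], rc[val]
        # re-center/scale the training fold so folds are self-contained
        Xt_s, mu_t, sd_t = _standardize(Xt)
        sd_t_safe = np.where(sd_t == 0.0, 1.0, sd_t)
        rt_c = rt - rt.mean()
        n_t = len(rt_c)
        G = Xt_s.T @ Xt_s / n_t
        c = Xt_s.T @ rt_c / n_t
        beta = np.zeros(p)
        for gi, lam in enumerate(grid):          # warm-started path
            beta = _cd_lasso(G, c, lam, beta, cfg.tol)
            pred = ((Xv - mu_t) / sd_t_safe) @ beta + rt.mean()
            fold_mse[f, gi] = np.mean((rv - pred) ** 2)
    cv_mse = fold_mse.mean(axis=0)
    best = int(np.argmin(cv_mse))  # first index => largest λ on ties
    if cfg.lambda_rule == "1se":
        se = float(np.std(fold_mse[:, best], ddof=1) / np.sqrt(cfg.cv_folds))
        best = int(np.argmax(cv_mse <= cv_mse[best] + se))

    G_full = Xs.T @ Xs / n
    c_full = Xs.T @ rc / n
    beta = np.zeros(p)
    for lam in grid[: best + 1]:
        beta = _cd_lasso(G_full, c_full, lam, beta, cfg.tol)
    active = [j for j in range(p) if abs(beta[j]) > 1e-10 and sd[j] > 0]
    return LassoResult(
        active=active,
        coef=beta,
        lam=float(grid[best]),
        lambda_grid=grid,
        cv_mse=cv_mse,
    )


def _ols_residual(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def isis_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ISISConfig | None = None,
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Iterative screening: screen vs y, lasso; then screen residuals, repeat.

    Iteration 1 screens all genes against the dose and lasso-selects among
    the top d.  Iteration k >= 2 regresses the dose on the current selected
    set, screens the remaining genes against the OLS residual, runs the lasso
    on the union, and replaces the selected set.  Stops when the set is
    unchanged or ``max_iter`` is reached.  The set is truncated to n - 2
    genes (largest |coefficient| kept) if the lasso overshoots.
    """
    cfg = cfg or ISISConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples for iterative screening")
    ids = gene_ids if gene_ids is not None else [f"g{j}" for j in range(p)]
    d = cfg.resolve_d(n, p)

    trace: list[dict] = []
    selected: list[int] = []
    marginal_full: np.ndarray | None = None

    for it in range(1, cfg.max_iter + 1):
        if it == 1:
            target = y
            candidates = np.arange(p)
        else:
            target = _ols_residual(X[:, selected], y)
            candidates = np.array(
                [j for j in range(p) if j not in set(selected)], dtype=int
            )
            if candidates.size == 0 or np.allclose(target, 0.0):
                trace.append(
                    {"iteration": it, "screened": [], "active": list(selected),
                     "residual_norm": float(np.linalg.norm(target)),
                     "note": "no candidates or zero residual"}
                )
                break
        # later passes recruit enough candidates to refill the screen budget
        # (classical iterative-screening bookkeeping), with a floor so that
        # conditional recruitment never starves once the set is full
        budget = d if it == 1 else min(d, max(5, d - len(selected)))
        d_it = min(budget, len(candidates))
        ranked, stat = marginal_screen(X[:, candidates], target, d_it)
        screened = candidates[ranked]
        if it == 1:
            marginal_full = stat
        pool = sorted(set(selected) | set(screened.tolist()))
        lasso = lasso_fit(X[:, pool], y, cfg, seed=seed + it)
        new_selected = [pool[j] for j in lasso.active]
        # order by |coefficient| (descending) for reporting and truncation
        order = np.argsort(
            [-abs(lasso.coef[pool.index(g)]) for g in new_selected],
            kind="mergesort",
        )
        new_selected = [new_selected[k] for k in order]
        entry = {
            "iteration": it,
            "screened": screened.tolist(),
            "active": list(new_selected),
            "residual_norm": float(np.linalg.norm(target)),
            "lambda": lasso.lam,
        }
        if len(new_selected) > n - 2:
            new_selected = new_selected[: n - 2]
            entry["warning"] = f"selected set truncated to n-2 = {n - 2}"
        trace.append(entry)
        if set(new_selected) == set(selected):
            selected = new_selected
            break
        selected = new_selected

    return SelectionResult(
        selected=[ids[j] for j in selected],
        selected_idx=list(selected),
        trace=trace,
        marginal_stats=marginal_full if marginal_full is not None else np.zeros(p),
    )


def ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient estimates and two-sided t-test p-values of OLS with intercept."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    dof = n - p - 1
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return coef[1:], pvals[1:]   # drop the intercept row


def variance_inflation(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) of regressing column j on the others."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if p < 2:
        return np.ones(p)
    out = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        resid = _ols_residual(others, X[:, j])
        tss = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        rss = float(resid @ resid)
        if tss <= 0:
            out[j] = 1.0
            continue
        r2 = 1.0 - rss / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def post_filter(
    X_sel: np.ndarray,
    y: np.ndarray,
    cfg: PostFilterConfig | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Prune a selected set by multicollinearity, then coefficient significance.

    Stage 1 repeatedly drops the gene with the largest VIF while any VIF
    exceeds ``vif_threshold`` (ties, including infinite VIFs from perfect
    collinearity, drop the later-indexed gene first).  Stage 2 fits OLS of
    the dose on the survivors and removes, in a single pass, every gene with
    coefficient p-value >= ``p_threshold``.  Returns the survivors and their
    p-values from the stage-2 fit.
    """
    cfg = cfg or PostFilterConfig()
    X_sel = np.atleast_2d(np.asarray(X_sel, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X_sel.shape
    if p >= n - 1:
        raise ValueError("selected set must be smaller than n - 1")
    ids = gene_ids if gene_ids is not None else [f"g{j}" for j in range(p)]
    keep = list(range(p))

    while len(keep) > 1:
        vif = variance_inflation(X_sel[:, keep])
        vmax = np.max(vif)
        if vmax <= cfg.vif_threshold:
            break
        # later-indexed gene goes first on ties
        worst = len(vif) - 1 - int(np.argmax(vif[::-1] == vmax))
        del keep[worst]

    _, pvals = ols_pvalues(X_sel[:, keep], y)
    final = [g for g, pv in zip(keep, pvals) if pv < cfg.p_threshold]
    final_p = np.array(
        [pv for pv in pvals if pv < cfg.p_threshold], dtype=float
    )
    return [ids[j] for j in final], final_p
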