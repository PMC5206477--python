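"""Metrics, cross-validated tuning and the repeated-holdout benchmark.

Performance is summarized by three quantities computed on the held-out
samples:

    RMSE = sqrt( sum_i (yhat_i - y_i)^2 / n )
    MAD  = sum_i |yhat_i - y_i| / n
    R^2  = 1 - SSE / SST,   SST about the evaluation-set mean

R^2 is computed about the test-set mean and may be negative when a model
does worse than predicting that mean; it is undefined (NaN) for a constant
observed vector.

The benchmark protocol repeats a random 70/30 split ``n_splits`` times (the
study convention is 100 splits and 50 bagging repetitions).  Within each
split, SVR and tree hyperparameters are tuned by 10-fold CV on the training
part and the tuned configurations are shared by the single and ensemble
variants of the same base learner within that split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, split_train_test
from .ensembles import GBMConfig, bagging_fit, bagging_predict, gbm_fit, gbm_predict, select_gbm_stages
from .learners import EpsilonSVR, RTConfig, RegressionTree, SVRConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Metrics",
    "EvalResult",
    "METHODS",
    "compute_metrics",
    "tune_svr",
    "tune_rt",
    "repeated_holdout",
    "permutation_gap_test",
]

METHODS = ("svr-linear", "svr-polynomial", "svr-bagging", "rt", "rt-bagging", "gbm")

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-2, 3))
DEFAULT_GAMMA_GRID = tuple(10.0 ** k for k in range(-3, 3))
DEFAULT_EPS_GRID = (0.05, 0.10, 0.20)
DEFAULT_RT_GRID = {
    "min_node_size": (2, 5, 10),
    "cp": (0.001, 0.01, 0.05),
    "max_depth": (2, 3, 5, 10),
}


@dataclass
class Metrics:
    rmse: float
    mad: float
    r2: float           # NaN when SST == 0
    n: int
    sse: float
    sst: float
    ssr: float


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """RMSE, MAD and test-set R^2 of predictions against observations."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D vectors of equal length")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    err = yhat - y
    sse = float(err @ err)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return Metrics(
        rmse=float(np.sqrt(sse / n)),
        mad=float(np.mean(np.abs(err))),
        r2=r2,
        n=n,
        sse=sse,
        sst=sst,
        ssr=sst - sse,
    )


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.permutation(np.arange(n) % folds)


def _cv_mse(make_est, X: np.ndarray, y: np.ndarray, fold_of: np.ndarray) -> float:
    sse = 0.0
    for f in range(fold_of.max() + 1):
        val = fold_of == f
        est = make_est().fit(X[~val], y[~val])
        sse += float(np.sum((y[val] - est.predict(X[val])) ** 2))
    return sse / len(y)


def _resolve_folds(n: int, folds: int) -> int:
    if n < folds:
        warnings.warn(
            f"fold count lowered from {folds} to {n} (too few samples)",
            stacklevel=3,
        )
        return n
    return folds


def tune_svr(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "linear",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    degree: int = 3,
    folds: int = 10,
    seed: int = 0,
) -> SVRConfig:
    """Grid search over (C, ε[, γ]) minimizing K-fold CV mean squared error.

    Folds are fixed across configurations; ties break toward smaller C then
    smaller ε (then smaller γ) by iterating the grid in increasing order
    with a strict-improvement rule.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = _resolve_folds(len(y), folds)
    fold_of = _fold_assignment(len(y), folds, seed)
    gammas = sorted(gamma_grid) if kernel == "polynomial" else [1.0]
    best_cfg, best_mse = None, np.inf
    for gamma in gammas:
        for eps in sorted(eps_grid):
            for C in sorted(C_grid):
                cfg = SVRConfig(
                    C=C, epsilon=eps, kernel=kernel, degree=degree, gamma=gamma
                )
                mse = _cv_mse(lambda: EpsilonSVR(cfg), X, y, fold_of)
                if mse < best_mse:
                    best_cfg, best_mse = cfg, mse
    return best_cfg


def tune_rt(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
) -> RTConfig:
    """Grid search over (min_node_size, cp, max_depth) by K-fold CV MSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = grid or DEFAULT_RT_GRID
    folds = _resolve_folds(len(y), folds)
    fold_of = _fold_assignment(len(y), folds, seed)
    best_cfg, best_mse = None, np.inf
    for mns in grid["min_node_size"]:
        for cp in grid["cp"]:
            for depth in grid["max_depth"]:
                cfg = RTConfig(min_node_size=mns, cp=cp, max_depth=depth)
                mse = _cv_mse(lambda: RegressionTree(cfg), X, y, fold_of)
                if mse < best_mse:
                    best_cfg, best_mse = cfg, mse
    return best_cfg


@dataclass
class EvalResult:
    per_split: pd.DataFrame     # columns: split, method, rmse, mad, r2
    summary: pd.DataFrame       # per-method mean/sd of each metric
    n_splits: int
    seed: int


def _summarize(per_split: pd.DataFrame) -> pd.DataFrame:
    agg = per_split.groupby("method")[["rmse", "mad", "r2"]].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def repeated_holdout(
    ds: ExpressionDataset,
    methods: Sequence[str],
    n_splits: int = 100,
    seed: int = 0,
    B: int = 50,
    train_fraction: float = 0.7,
    tune: bool = True,
    tune_folds: int = 10,
    tune_per_split: bool = True,
    gbm_config: GBMConfig | None = None,
    gbm_stage_grid: Sequence[int] | None = None,
) -> EvalResult:
    """Repeated random 70/30 evaluation of the requested methods.

    Split k uses seed ``seed + k``, so the per-split results form a
    prefix-stable stream: increasing ``n_splits`` never changes earlier
    rows.  Tuned configurations are shared between a base learner and its
    bagged variant within the same split.  A method failing on a split is
    recorded as missing and the run continues.  ``tune_per_split=False``
    tunes once on the first split's training part and reuses the
    configurations everywhere.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method '{m}' (choose from {METHODS})")
    gbm_config = gbm_config or GBMConfig()
    need_lin = any(m in ("svr-linear", "svr-bagging") for m in methods)
    need_poly = "svr-polynomial" in methods
    need_rt = any(m in ("rt", "rt-bagging") for m in methods)

    rows = []
    cached: dict[str, object] = {}
    for k in range(n_splits):
        split_seed = seed + k
        pair = split_train_test(ds, train_fraction, seed=split_seed)
        Xtr, ytr = pair.train.X, pair.train.y
        Xte, yte = pair.test.X, pair.test.y

        if tune and (tune_per_split or not cached):
            cfgs = {}
            if need_lin:
                cfgs["svr-linear"] = tune_svr(
                    Xtr, ytr, "linear", folds=tune_folds, seed=split_seed
                )
            if need_poly:
                cfgs["svr-polynomial"] = tune_svr(
                    Xtr, ytr, "polynomial", folds=tune_folds, seed=split_seed
                )
            if need_rt:
                cfgs["rt"] = tune_rt(Xtr, ytr, folds=tune_folds, seed=split_seed)
            if "gbm" in methods and gbm_stage_grid is not None:
                m_best = select_gbm_stages(
                    Xtr, ytr, gbm_config, grid=gbm_stage_grid,
                    folds=tune_folds, seed=split_seed,
                )
                cfgs["gbm"] = GBMConfig(
                    M=m_best, nu=gbm_config.nu,
                    max_depth=gbm_config.max_depth,
                    min_node_size=gbm_config.min_node_size,
                )
            cached = cfgs
        cfgs = cached if tune else {}
        lin_cfg = cfgs.get("svr-linear", SVRConfig())
        rt_cfg = cfgs.get("rt", RTConfig())
        g_cfg = cfgs.get("gbm", gbm_config)

        for method in methods:
            try:
                if method == "svr-linear":
                    yhat = EpsilonSVR(lin_cfg).fit(Xtr, ytr).predict(Xte)
                elif method == "svr-polynomial":
                    cfg = cfgs.get(
                        "svr-polynomial", SVRConfig(kernel="polynomial")
                    )
                    yhat = EpsilonSVR(cfg).fit(Xtr, ytr).predict(Xte)
                elif method == "svr-bagging":
                    model = bagging_fit(
                        Xtr, ytr, EpsilonSVR(lin_cfg), B=B,
                        seed=split_seed * 1000,
                    )
                    yhat = bagging_predict(model, Xte)
                elif method == "rt":
                    yhat = RegressionTree(rt_cfg).fit(Xtr, ytr).predict(Xte)
                elif method == "rt-bagging":
                    model = bagging_fit(
                        Xtr, ytr, RegressionTree(rt_cfg), B=B,
                        seed=split_seed * 1000,
                    )
                    yhat = bagging_predict(model, Xte)
                elif method == "gbm":
                    yhat = gbm_predict(gbm_fit(Xtr, ytr, g_cfg), Xte)
                met = compute_metrics(yte, yhat)
                rows.append(
                    {"split": k, "method": method, "rmse": met.rmse,
                     "mad": met.mad, "r2": met.r2}
                )
            except Exception as exc:  # failure leaves a hole, run continues
                logger.warning("method %s failed on split %d: %s", method, k, exc)
                rows.append(
                    {"split": k, "method": method, "rmse": np.nan,
                     "mad": np.nan, "r2": np.nan}
                )

    per_split = pd.DataFrame(rows)
    return EvalResult(
        per_split=per_split,
        summary=_summarize(per_split),
        n_splits=n_splits,
        seed=seed,
    )


def permutation_gap_test(
    ds: ExpressionDataset,
    method: str,
    n_perms: int = 999,
    n_splits: int = 10,
    seed: int = 0,
    **holdout_kwargs,
) -> dict:
    """Extension (not part of the study protocol): permutation check that a
    method's mean test R^2 exceeds chance.

    Shuffles the dose vector ``n_perms`` times, reruns the holdout each
    time, and reports the fraction of permuted runs whose mean R^2 reaches
    the observed one.
    """
    observed = repeated_holdout(
        ds, [method], n_splits=n_splits, seed=seed, **holdout_kwargs
    )
    obs_r2 = float(observed.per_split["r2"].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for b in range(n_perms):
        perm = ExpressionDataset(
            sample_ids=list(ds.sample_ids),
            gene_ids=list(ds.gene_ids),
            X=ds.X,
            y=rng.permutation(ds.y),
            meta=dict(ds.meta),
        )
        res = repeated_holdout(
            perm, [method], n_splits=n_splits, seed=seed, **holdout_kwargs
        )
        if float(res.per_split["r2"].mean()) >= obs_r2:
            count += 1
    return {
        "method": method,
        "observed_mean_r2": obs_r2,
        "p_value": (count + 1) / (n_perms + 1),
        "n_perms": n_perms,
    }
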