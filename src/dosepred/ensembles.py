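"""Bootstrap aggregation and squared-loss gradient boosting.

Bagging is generic over any estimator exposing ``fit(X, y)`` /
``predict(X)`` / ``clone()`` (both shipped learners qualify), so the same
machinery bags regression trees and ε-SVR models.  Each member is trained on
a full-size bootstrap resample (drawn with replacement, seeded per member as
``seed + b``) and the ensemble prediction is the unweighted mean of member
predictions — the regression-bagging convention.

Gradient boosting is the squared-loss stagewise variant: start from the
constant training mean, repeatedly fit a depth-limited regression tree to
the current residuals (the negative gradient of the squared loss) and add it
scaled by the shrinkage ``nu``.  The training loss after each stage is
recorded and is non-increasing for ``nu <= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .learners import RTConfig, TreeNode, rt_fit, rt_predict

__all__ = [
    "BaseLearner",
    "BaggingModel",
    "GBMConfig",
    "GBMModel",
    "bagging_fit",
    "bagging_predict",
    "gbm_fit",
    "gbm_predict",
    "gbm_staged_predict",
    "select_gbm_stages",
]


class BaseLearner(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaseLearner": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...
    def clone(self) -> "BaseLearner": ...


@dataclass
class BaggingModel:
    members: list
    B: int
    base_config: object
    seeds: list[int]


def bagging_fit(
    X: np.ndarray,
    y: np.ndarray,
    base: BaseLearner,
    B: int = 50,
    seed: int = 0,
    sample_indices: Callable[[int, np.random.Generator], np.ndarray] | None = None,
) -> BaggingModel:
    """Fit ``B`` copies of ``base`` on bootstrap resamples of (X, y).

    ``sample_indices`` is a test hook: given (n, rng) it returns the row
    indices for one member (default: n i.i.d. uniform draws with
    replacement).  A resample with constant response is legitimate — the
    member simply degenerates to a constant predictor.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    members, seeds = [], []
    for b in range(B):
        member_seed = seed + b
        rng = np.random.default_rng(member_seed)
        idx = (
            sample_indices(n, rng)
            if sample_indices is not None
            else rng.integers(0, n, size=n)
        )
        member = base.clone().fit(X[idx], y[idx])
        members.append(member)
        seeds.append(member_seed)
    return BaggingModel(
        members=members,
        B=B,
        base_config=getattr(base, "config", None),
        seeds=seeds,
    )


def bagging_predict(model: BaggingModel, X: np.ndarray) -> np.ndarray:
    """Row-wise arithmetic mean of member predictions."""
    preds = np.stack([m.predict(X) for m in model.members])
    return preds.mean(axis=0)


@dataclass
class GBMConfig:
    """Stagewise boosting controls: stages M, shrinkage nu, stage-tree shape."""

    M: int = 100
    nu: float = 0.1
    max_depth: int = 3
    min_node_size: int = 5

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must lie in (0, 1]")

    def stage_tree_config(self) -> RTConfig:
        # cp = 0: residual trees are gated by depth/size only
        return RTConfig(
            min_node_size=self.min_node_size, cp=0.0, max_depth=self.max_depth
        )


@dataclass
class GBMModel:
    f0: float
    stages: list[TreeNode]
    nu: float
    M: int
    stage_losses: np.ndarray   # mean squared training loss after each stage
    config: GBMConfig


def gbm_fit(X: np.ndarray, y: np.ndarray, cfg: GBMConfig | None = None) -> GBMModel:
    """Squared-loss gradient boosting of regression trees."""
    cfg = cfg or GBMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    f0 = float(y.mean())
    f = np.full(len(y), f0)
    tree_cfg = cfg.stage_tree_config()
    stages: list[TreeNode] = []
    losses = np.empty(cfg.M)
    for m in range(cfg.M):
        resid = y - f
        tree = rt_fit(X, resid, tree_cfg)
        f = f + cfg.nu * rt_predict(tree, X)
        stages.append(tree)
        losses[m] = float(np.mean((y - f) ** 2))
    return GBMModel(
        f0=f0, stages=stages, nu=cfg.nu, M=cfg.M, stage_losses=losses, config=cfg
    )


def gbm_predict(model: GBMModel, X: np.ndarray) -> np.ndarray:
    """Evaluate the additive expansion f0 + nu * sum_m tree_m(x)."""
    X = np.asarray(X, dtype=float)
    out = np.full(X.shape[0], model.f0)
    for tree in model.stages:
        out += model.nu * rt_predict(tree, X)
    return out


def gbm_staged_predict(model: GBMModel, X: np.ndarray) -> np.ndarray:
    """Predictions after each stage, shape (M, n_rows); stage 0 excluded."""
    X = np.asarray(X, dtype=float)
    out = np.empty((model.M, X.shape[0]))
    f = np.full(X.shape[0], model.f0)
    for m, tree in enumerate(model.stages):
        f = f + model.nu * rt_predict(tree, X)
        out[m] = f
    return out


def select_gbm_stages(
    X: np.ndarray,
    y: np.ndarray,
    cfg: GBMConfig | None = None,
    grid: Sequence[int] = (50, 100, 150, 200, 250, 300, 350, 400, 450, 500),
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Choose the stage count M by K-fold CV over a grid.

    One boosted model per fold is fit at ``max(grid)`` and its staged
    predictions are scored at every candidate, so the grid costs a single
    fit per fold.  Ties break toward smaller M.
    """
    cfg = cfg or GBMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = min(folds, n)
    grid = sorted(set(int(g) for g in grid))
    m_max = grid[-1]
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(n) % folds)
    sse = np.zeros(len(grid))
    for f in range(folds):
        val = fold_of == f
        model = gbm_fit(
            X[~val],
            y[~val],
            GBMConfig(
                M=m_max,
                nu=cfg.nu,
                max_depth=cfg.max_depth,
                min_node_size=cfg.min_node_size,
            ),
        )
        staged = gbm_staged_predict(model, X[val])
        for gi, m in enumerate(grid):
            sse[gi] += np.sum((y[val] - staged[m - 1]) ** 2)
    return grid[int(np.argmin(sse))]
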