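"""Monte-Carlo sample-size sweep: single tree vs bagging vs boosting.

For each training-set size n in a grid, many replicates are drawn from the
correlated dose+gene generator; each replicate fits a single regression
tree, a bagged ensemble of B trees and a boosted ensemble on the training
draw, predicts a large fresh test draw, back-transforms predictions and
observed doses to raw units via the affine dose scaler, and records RMSE
and MAD.  Per-size means locate the training size from which bagging
sustainably outperforms the single tree (the "cutoff").

Seeding: replicate (n, r) draws its generator stream from
``SeedSequence(master_seed, spawn_key=(n, r))``, so results for one size
are unchanged by adding or removing other sizes from the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensembles import GBMConfig, bagging_fit, bagging_predict, gbm_fit, gbm_predict
from .learners import RTConfig, RegressionTree, rt_fit, rt_predict
from .synthetic import (
    SyntheticConfig,
    build_correlation_matrix,
    generate_mvn,
    gse2409_like_config,
    to_raw_dose,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig",
    "SweepResult",
    "CutoffReport",
    "run_sweep",
    "detect_cutoff",
]

SWEEP_METHODS = ("rt", "rt-bagging", "gbm")


@dataclass
class SweepConfig:
    """The sweep design: generator template, size grid, replicate count."""

    data_config: SyntheticConfig = field(default_factory=gse2409_like_config)
    train_sizes: tuple[int, ...] = (15, 20, 25, 30, 35, 40, 45, 50, 55, 60)
    reps: int = 500
    test_size: int = 1000
    rt_config: RTConfig = field(default_factory=lambda: RTConfig(min_node_size=5, cp=0.01, max_depth=10))
    B: int = 50
    gbm_config: GBMConfig = field(default_factory=lambda: GBMConfig(M=100, nu=0.1, max_depth=3, min_node_size=5))
    master_seed: int = 0
    keep_raw: bool = True

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.train_sizes)
        if any(s < 5 for s in sizes) or any(
            b <= a for a, b in zip(sizes, sizes[1:])
        ):
            raise ValueError("train_sizes must be strictly increasing, all >= 5")
        self.train_sizes = sizes
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class SweepResult:
    table: pd.DataFrame         # train_size x method: mean/sd of rmse and mad
    raw: pd.DataFrame | None    # per-replicate records (train_size, rep, method, rmse, mad)
    config: SweepConfig


@dataclass
class CutoffReport:
    cutoff_n: int | None
    margin: float
    better: str
    baseline: str
    per_size: pd.DataFrame      # size, mean_diff (baseline - better), CI bounds


def _rep_seeds(master: int, n: int, r: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(master, spawn_key=(n, r))
    train_seed, test_seed = ss.generate_state(2)
    return int(train_seed % (2**31)), int(test_seed % (2**31))


def run_sweep(cfg: SweepConfig) -> SweepResult:
    """Run the sweep; RMSE/MAD are in raw dose units after back-transform."""
    sigma = build_correlation_matrix(cfg.data_config.spec)
    scaler = cfg.data_config.scaler
    records = []
    for n in cfg.train_sizes:
        failures = 0
        for r in range(cfg.reps):
            train_seed, test_seed = _rep_seeds(cfg.master_seed, n, r)
            train = generate_mvn(sigma, n, train_seed)
            test = generate_mvn(sigma, cfg.test_size, test_seed)
            Xtr, ztr = train[:, 1:], train[:, 0]
            Xte, zte = test[:, 1:], test[:, 0]
            y_te = np.asarray(to_raw_dose(zte, scaler))
            try:
                tree = rt_fit(Xtr, ztr, cfg.rt_config)
                preds = {"rt": rt_predict(tree, Xte)}
                bag = bagging_fit(
                    Xtr, ztr, RegressionTree(cfg.rt_config), B=cfg.B,
                    seed=train_seed,
                )
                preds["rt-bagging"] = bagging_predict(bag, Xte)
                boosted = gbm_fit(Xtr, ztr, cfg.gbm_config)
                preds["gbm"] = gbm_predict(boosted, Xte)
            except Exception as exc:
                failures += 1
                logger.warning("replicate (n=%d, r=%d) failed: %s", n, r, exc)
                for method in SWEEP_METHODS:
                    records.append(
                        {"train_size": n, "rep": r, "method": method,
                         "rmse": np.nan, "mad": np.nan}
                    )
                continue
            for method, zhat in preds.items():
                err = np.asarray(to_raw_dose(zhat, scaler)) - y_te
                records.append(
                    {
                        "train_size": n,
                        "rep": r,
                        "method": method,
                        "rmse": float(np.sqrt(np.mean(err**2))),
                        "mad": float(np.mean(np.abs(err))),
                    }
                )
        if failures > 0.05 * cfg.reps:
            raise RuntimeError(
                f"{failures}/{cfg.reps} replicates failed at train size {n}"
            )
    raw = pd.DataFrame(records)
    table = (
        raw.groupby(["train_size", "method"])[["rmse", "mad"]]
        .agg(["mean", "std"])
    )
    table.columns = [f"{m}_{s}" for m, s in table.columns]
    table = table.rename(
        columns={
            "rmse_mean": "mean_rmse", "rmse_std": "sd_rmse",
            "mad_mean": "mean_mad", "mad_std": "sd_mad",
        }
    ).reset_index()
    return SweepResult(table=table, raw=raw if cfg.keep_raw else None, config=cfg)


def detect_cutoff(
    res: SweepResult,
    better: str = "rt-bagging",
    baseline: str = "rt",
    margin: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> CutoffReport:
    """Smallest grid size from which ``better`` beats ``baseline`` for good.

    The cutoff is the smallest size n* with
    ``mean_rmse(better) < mean_rmse(baseline) - margin`` at n* *and every
    larger grid size* — a sustained crossing, so one noisy dip does not
    declare victory.  Per-size mean differences (baseline - better, positive
    favours ``better``) carry percentile-bootstrap 95% CIs over replicates
    when raw records are available.
    """
    table = res.table
    sizes = sorted(table["train_size"].unique())
    for m in (better, baseline):
        present = set(table.loc[table["method"] == m, "train_size"])
        if not set(sizes) <= present:
            raise ValueError(f"method '{m}' missing at some train sizes")

    def mean_rmse(method: str, n: int) -> float:
        sel = (table["method"] == method) & (table["train_size"] == n)
        return float(table.loc[sel, "mean_rmse"].iloc[0])

    wins = [mean_rmse(better, n) < mean_rmse(baseline, n) - margin for n in sizes]
    cutoff_n = None
    for i, n in enumerate(sizes):
        if all(wins[i:]):
            cutoff_n = int(n)
            break

    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        diff = mean_rmse(baseline, n) - mean_rmse(better, n)
        lo = hi = np.nan
        if res.raw is not None:
            sub = res.raw[res.raw["train_size"] == n]
            a = sub[sub["method"] == baseline].set_index("rep")["rmse"]
            b = sub[sub["method"] == better].set_index("rep")["rmse"]
            paired = (a - b).dropna().to_numpy()
            if len(paired):
                idx = rng.integers(0, len(paired), size=(n_boot, len(paired)))
                boots = paired[idx].mean(axis=1)
                lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {"train_size": n, "mean_diff": diff,
             "ci_low": float(lo), "ci_high": float(hi)}
        )
    return CutoffReport(
        cutoff_n=cutoff_n,
        margin=margin,
        better=better,
        baseline=baseline,
        per_size=pd.DataFrame(rows),
    )
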