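# dosepred

Predicting continuous clinical doses — drug doses, nutrient or metal
concentrations — from gene-expression profiles, and asking when tree
ensembles are worth it: at what training-set size does bagging of
regression trees start to beat a single tree?

The package is aimed at biostatisticians working with small
dose-response microarray studies (tens of samples, thousands of genes).
It provides, as tested library code under `src/dosepred/`:

- **Feature selection**: iterative sure-independence screening — rank genes
  by marginal |Pearson correlation| with the dose, keep the top
  `d = ⌊n/ln n⌋`, refine with a cross-validated coordinate-descent lasso,
  iterate on OLS residuals to catch marginally weak but jointly relevant
  genes — plus a VIF/significance post-filter.
- **Learners, written from scratch**: an exact greedy CART regression tree
  (split minimising `min_{j,s} [min_c1 Σ_{x∈R1}(y−c1)² + min_c2 Σ_{x∈R2}(y−c2)²]`,
  leaves predicting region means) and ε-insensitive support vector
  regression (minimise `½‖w‖² + (C/N) Σ L_ε(y_i, f(x_i))`, dual solved by
  SMO, linear and polynomial kernels).
- **Ensembles**: bootstrap aggregation generic over both learners
  (B = 50, mean combination) and squared-loss gradient boosting
  (stagewise residual-fitting trees, shrinkage ν = 0.1).
- **Evaluation**: RMSE, MAD and test-set R², 10-fold-CV hyperparameter
  tuning, and a repeated 70/30 holdout harness (100 splits by convention).
- **Simulation**: a multivariate-normal dose+gene generator driven by a
  correlation matrix with an affine dose back-transform
  (`y = z·σ_y + ȳ`), a p ≫ n sparse-signal generator, and a Monte-Carlo
  training-size sweep with sustained-crossing cutoff detection.

A GEO Series Matrix adapter is included for pointing the pipeline at real
series; the repository itself is fully buildable and testable offline on
synthetic data.

## Worked example

```python
import numpy as np
from dosepred.synthetic import generate_dataset, gse2409_like_config
from dosepred.evaluation import repeated_holdout

ds = generate_dataset(gse2409_like_config())   # 69 samples x 8 genes
res = repeated_holdout(ds, ["svr-linear", "rt", "rt-bagging", "gbm"],
                       n_splits=20, seed=0)
print(res.per_split.groupby("method")[["rmse", "r2"]].mean().round(3))
```

prints (doses in raw units, scaler mean 13.60 / sd 9.59):

```
             rmse     r2
method
gbm         6.116  0.523
rt          8.866 -0.017
rt-bagging  6.389  0.485
svr-linear  4.900  0.691
```

The generator's dose is a linear function of eight correlated genes with
population R² ≈ 0.79, so the linear-kernel SVR sits on top (mean test R²
0.69 at n = 69), boosting and bagging follow, and the single tree trails —
the ordering expected for linear signal at this sample size.  RMSE is in
raw dose units (test-set doses have sd ≈ 9.6).

The numbered drivers under `analysis/` run the full story:
`01_simulate_data.py` (draw and describe the reference dataset),
`02_select_features.py` (screening recovery in a p ≫ n design),
`03_benchmark_methods.py` (all six methods under repeated holdout),
`04_sample_size_sweep.py` (learning curves and the bagging cutoff); each
writes its tables under `results/`. The same stages are exposed as a CLI:

```bash
dosepred simulate-data --preset gse2409-like --seed 1 --out data.tsv
dosepred select   --input data.tsv --seed 1 --out selected.json
dosepred evaluate --input data.tsv --methods svr-linear,rt,rt-bagging,gbm \
                  --splits 100 --bags 50 --seed 1 --out results.csv
dosepred simulate --reps 500 --seed 1 --out sweep.csv --cutoff-report cutoff.json
dosepred report   --evaluate-csv results.csv --sweep-csv sweep.csv --out-dir report/
```

Every run writes a `run_manifest.json`; identical manifests give
byte-identical outputs.

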