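# Methods

This package studies how well a continuous clinical dose (a drug dose, a
nutrient or metal concentration) can be predicted from gene-expression
profiles, and in particular how the relative merit of single regression
trees, bagged trees and boosted trees depends on the training-set size.
Everything runs on synthetic data whose correlation structure emulates a
small rat microarray study; an optional GEO Series Matrix adapter lets the
same pipeline be pointed at real series.

## Data model

A dataset is an `n x p` matrix of log2-scale expression values plus a
continuous response `y`.  Preprocessing maps raw intensities through
`log2(max(v, 0) + 1)` (the pseudo-count keeps the transform total on
background-corrected values that can be zero or negative), drops genes whose
missing fraction exceeds 0.2 (configurable) and median-imputes the rest.
Evaluation always uses random 70/30 train/test splits with the training size
rounded half-away-from-zero.

## Synthetic generator

The correlated generator draws i.i.d. rows from `N(0, Sigma)` where `Sigma`
is a `(q+1) x (q+1)` correlation matrix: component 0 is the standardized
dose `z`, components 1..q are genes.  Raw doses are recovered by the affine
map `y = z * sigma_y + ybar`.  The reference configuration uses q = 8
genes, dose–gene correlation 0.52, gene–gene correlation 0.25 and the
scaler (13.60, 9.59); the implied population R² of the dose given the genes
is `q rho² / (1 + (q-1) r) ≈ 0.787`, chosen to echo the ≈0.81
predictability of the real study this configuration emulates.  The true
9×9 correlation matrix of that study is not public, so all conclusions tied
to this stand-in are qualitative: the generator reproduces the *linear,
moderately correlated, moderately predictable* character of the data, not
its exact levels.  In particular it has Gaussian genes and a purely linear
dose signal — real expression data are heavier-tailed, and real dose
responses can saturate — so passing tests say nothing about nonlinear
real-data structure.  Infeasible correlation specs are repaired by clipping
eigenvalues at 1e-6 and rescaling to unit diagonal.

A second generator produces `p >> n` sparse designs (independent standard
normal genes, k of them with a linear effect) to exercise feature selection.

## Feature selection

Iterative sure-independence screening: rank genes by marginal |Pearson
correlation| with the dose, keep the top `d = floor(n / ln n)`, run a
coordinate-descent lasso with 10-fold cross-validation on the screened set,
and keep the active genes.  Later passes regress the dose on the current
selection (OLS), screen the remaining genes against the residual, and rerun
the lasso on the union; iteration stops when the selection stabilises or
after 5 passes.  Design choices that the procedure's name does not fix:

- λ follows the one-standard-error rule on the CV curve (the conventional
  sparser choice); the plain CV minimiser is available via
  `lambda_rule="min"`.
- Later passes recruit `min(d, max(5, d - |selected|))` candidates: the
  refill rule keeps the working pool near `d`, and the floor of five keeps
  conditional recruitment alive once the pool is full — with a single
  recruit slot, a marginally invisible but jointly relevant gene can be
  crowded out by one decoy.
- The post-filter first drops the gene with the largest variance-inflation
  factor while any VIF exceeds 10 (ties and perfect collinearity drop the
  later-indexed gene), then removes genes with OLS coefficient p ≥ 0.10 in
  a single pass.  The 0.10 cut matches the borderline coefficients
  (p ≈ 0.069) retained in the study the pipeline emulates.

A known limitation, measured rather than assumed: in the hard regime
(n=100, p=1000, eight effects of 0.5 against unit noise) roughly 6–7 of the
8 true genes are recovered in a typical replicate, and the ≥7/8 recovery
rate plateaus near 60–70% — for this implementation, for scikit-learn's
LassoCV dropped into the same iteration, and for several variants
(significance-restricted conditioning, lasso-residual screening, backward
elimination).  An oracle whose selection step keeps exactly the true genes
recovers everything, which localises the barrier: screening retains decoys
whose in-sample correlation is genuinely large, any CV-chosen lasso keeps
them, and they pollute the residual used for later screening passes.

## Learners

**Regression tree.** Exact greedy CART: every node scans all features and
all midpoints between consecutive distinct sorted values and takes the
split minimising the summed child SSE, computed from cumulative sums in
O(n p) per node.  Near-ties (within `1e-9 * y'y`) resolve toward the
smallest feature index then the smallest split point, and `x_j == s` routes
left; these conventions are pinned so an exhaustive-search oracle can check
the implementation exactly.  A split must reduce SSE by at least
`cp * SST_root` (CART-style gate against the root sum of squares), keep
both children at `min_node_size` or larger, and respect `max_depth`.
Leaves predict the mean response of their region.

**ε-insensitive SVR.** Minimises `1/2 ||w||² + (C/N) Σ L_eps` where the
loss is zero inside a tube of half-width ε and linear outside.  Because the
loss carries an explicit 1/N, the dual box bound is `C/N`; published C
grids are therefore implementation-relative, and cross-checks against
libsvm use `C_libsvm = C/N`.  The dual is solved by SMO with
maximal-violating-pair working-set selection on the 2n-variable
(α, α*) formulation, stopping when the KKT violation falls below 1e-8;
per-sample complementarity (never both α and α* active) is enforced by
subtracting the pairwise minimum, which preserves the solution.  The bias
is the mean KKT-implied value over free support vectors, falling back to
the midpoint of the feasible interval when every multiplier is at a bound.
Kernels: linear and polynomial `(gamma <x,x'> + coef0)^degree` (coef0
defaults to 1 so the default polynomial kernel is inhomogeneous); radial
and sigmoid kernels are deliberately out of scope.

## Ensembles

Bagging is generic over any fit/predict/clone estimator: B = 50 members by
default, each trained on a full-size bootstrap resample (member b seeded
`seed + b`), predictions combined by the unweighted mean — the regression
convention; weighted-median combination belongs to the AdaBoost.R family,
which is not implemented.  Gradient boosting is the squared-loss stagewise
variant: start from the training mean, fit a depth-3 tree (cp = 0,
min_node_size = 5) to the residuals, add it scaled by nu = 0.1, repeat
M = 100 times.  Stage losses are recorded and are non-increasing for
nu ≤ 1.  A staged-prediction CV selector for M over {50..500} is provided
(`select_gbm_stages`, one fit per fold scored at every candidate); the
benchmark harness defaults to the fixed M = 100 for tractability and
exposes the CV route via `gbm_stage_grid`.

## Evaluation protocol

Metrics: RMSE, MAD and R² = 1 − SSE/SST with SST about the *test-set* mean;
R² can be negative and is NaN for a constant test response.  The benchmark
repeats a seeded 70/30 split (split k uses seed `master + k`, so the
per-split stream is prefix-stable), tunes SVR
(C ∈ 10^{-2..2}, ε ∈ {0.05, 0.10, 0.20}, γ ∈ 10^{-3..2} for the polynomial
kernel) and the tree (min_node_size ∈ {2,5,10}, cp ∈ {0.001,0.01,0.05},
depth ∈ {2,3,5,10}) by 10-fold CV on the training part, shares the tuned
configuration between a learner and its bagged variant within the split,
and averages metrics over splits (study convention: 100 splits, 50 bagging
members).  Ties in CV error break toward smaller C, then smaller ε/γ.
Whether tuning should be per split or once per dataset is ambiguous in the
protocol being emulated; per split is the default, `tune_per_split=False`
gives the other reading.  A labelled extension (`permutation_gap_test`)
permutes the dose to calibrate a method's mean R² against chance; it is not
part of the core protocol.

## Sample-size sweep

For each training size n in {15, 20, ..., 60} (a grid bracketing the
cutoff region and the real studies' 15–98 sample sizes) and each of
`reps` replicates, the sweep draws a fresh size-n training set and a fresh
1000-sample test set from the generator, fits the single tree
(min_node_size 5, cp 0.01, depth 10), the 50-member bagged tree and the
fixed-M GBM on the standardized dose, back-transforms predictions to raw
dose units, and records RMSE and MAD.  The large fixed test draw is a
design choice that minimises evaluation noise; the emulated study does not
state its evaluation-set size.  Replicate (n, r) seeds its generator from
`SeedSequence(master, spawn_key=(n, r))`, so per-size results are invariant
to the rest of the grid.  The cutoff is the smallest grid size from which
the bagged ensemble's mean RMSE stays below the single tree's at *every*
larger size (sustained crossing; a margin parameter is available), with
percentile-bootstrap 95% CIs on the per-size differences.  With the
equicorrelated stand-in matrix the bagging advantage is already positive at
n = 15 and grows with n, so the detected cutoff sits at the bottom of the
grid; the exact crossing point reported for the real data is a property of
the unpublished correlation matrix and is not reproduced quantitatively.

## Problem sizes used by the shipped runs

The analysis drivers and the acceptance script scale the Monte-Carlo work
to desk size as the package's own defaults: 20 holdout splits, 10–20
screening replicates, and 100–200 sweep replicates over sizes
{15, 25, 40, 55, 60} (the full grid at `--reps 500` reproduces the complete
experiment).  Numerical tolerances: lasso coordinate updates converge at
1e-7; SMO stops at KKT violation 1e-8; split near-ties at `1e-9 * y'y`;
positive-definiteness repair clips eigenvalues at 1e-6.

## Known limitations

- The stand-in correlation matrix makes all sweep conclusions qualitative.
- Screening recovery in the hard sparse regime plateaus below the
  sure-screening ideal (see above); the post-filter inherits whatever the
  screen hands it.
- The SVR C grid is tied to the C/N loss scaling; comparisons with
  implementations that use C as the per-sample bound must rescale.
- No real-data claims: the GEO adapter parses the format, but no accession
  is downloaded, and significance stars / per-accession gene lists of the
  emulated study are data-dependent and out of scope.
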