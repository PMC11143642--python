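# Methods

This note records the models, the numerical choices, and the limits of what
the package's tests demonstrate.

## Synthetic data generator

The raw replicate data of the underlying factorial experiment were never
deposited; only per-treatment-cell summaries (mean ± SD, n = 20) are
available, packaged as `data/table3_stats.csv` (192 records = 3 cultivars ×
16 dose cells × 4 traits). The generator draws each cell's replicates from
Normal(mean, sd) and clips to the trait's valid range — ES to [0, 100];
LN, PR, SL to [0, ∞). Cells with sd = 0 (e.g. survival pinned at 100%)
return the exact constant. Clipping rather than resampling keeps the draw
count per cell fixed, so results are reproducible cell-by-cell; clipping
events are logged. Leaf counts are kept real-valued: the published means
are fractional and nothing identifies the raw replicates as integers.

Randomness: one root seed; each cell uses a substream keyed by a CRC of
(cultivar, GA₃, ZT, trait), so a cell's draws are identical whether one
cultivar or all three are generated.

What the generator does **not** emulate: within-explant correlation among
the four traits (no covariance information exists), any non-normality of
the real replicates, and integer-valued counts. Pipeline results on
generated data therefore validate the *machinery* (tuning, stacking,
ranking, optimization) and the qualitative response surface, not the exact
published predictions, which depended on the study's unavailable raw data.

## Preprocessing

Only the two dose features are standardized (`z = (x − μ)/σ`, population
σ), with moments estimated on the training rows alone and reused unchanged
for test rows and dose grids; responses stay in trait units because the
evaluation statistics are defined on raw units. Each cultivar's 320 rows
are split 80/20 independently (models are per-cultivar), and the training
rows are partitioned into K = 10 folds with sizes differing by at most one.
The outlier screen flags rows beyond 3 SD on either of the first two
principal components of the z-scored response matrix; it reports, never
drops — on generated data a handful of flags out of 960 rows is ordinary
sampling behavior.

## Surrogates and stacking

SVR (RBF kernel), random forest, gradient-boosted trees and elastic-net
linear regression are delegated to scikit-learn / xgboost behind a single
fit/predict contract; hyperparameters are validated against the search
spaces below before any fit. SVR targets are internally z-scored and
back-transformed, because its ε-tube is scale-sensitive and the ε search
range is fixed; this is recorded in the model record. ENMLR with α = 0
falls back to ordinary least squares (coordinate descent is undefined
there). Predictions at raw dose pairs are clipped to the trait's valid
range at report time and refuse doses outside the experimental rectangle
unless extrapolation is explicitly enabled — tree and kernel surrogates
carry no information beyond the tested range.

Search spaces (TPE-tuned, 10-fold CV RMSE objective):

| model | dimensions |
|---|---|
| XGB | n_estimators [10,1500]ℤ, learning_rate [0.001,0.3], gamma [0,10], max_depth [1,20]ℤ, subsample [0.001,1], colsample_bytree [0.01,1], min_child_weight [1,10], reg_lambda [0,5], reg_alpha [0,5] |
| RF | n_estimators [10,1500]ℤ, max_features (0,1], max_depth [2,50]ℤ, min_samples_split [1,100]ℤ, min_samples_leaf [1,15]ℤ, min_weight_fraction_leaf [0,0.5], max_leaf_nodes [2,200]ℤ |
| ENMLR | alpha [0,5], l1_ratio [0,1] |
| SVR | gamma (0,10], C (0,50], epsilon (0,5] |

(`min_samples_split = 1` is accepted by the space but floored to
scikit-learn's minimum of 2 at estimator construction.)

The stacking ensemble (ESR) uses XGB, SVR and ENMLR as base regressors and
an RF meta-regressor. Meta-features are **out-of-fold** base predictions
over the same 10 folds used for tuning — the leakage-safe construction: no
base prediction for a row comes from a model that saw that row. The bases
are then refitted on the full training set for test-time meta-features.
The meta-RF uses fixed defaults (300 trees, unconstrained depth) rather
than its own tuning round: a forest on a 3-column meta-feature matrix is
insensitive to its hyperparameters here, and tuning a meta-learner on
reused out-of-fold features invites overfitting the folds themselves.

## Hyperparameter tuning

The tuner is a tree-structured Parzen estimator written for this package:
10 random warm-up evaluations, then the history is split at the 25%
objective quantile; each dimension gets a Parzen density (Gaussian mixture
with neighbor-spacing bandwidths plus a 5% uniform floor) over the good and
bad groups; 24 candidates are drawn from the good density and the one
maximizing the density ratio is evaluated. Integer dimensions are quantized
at sampling. The design guarantees two useful properties, both tested: the
evaluation sequence at budget B is a prefix of the sequence at any larger
budget (same seed), and every evaluated configuration lies inside the
declared space. On a convex 1-D toy the tuner beats budget-matched random
search in the large majority of paired seeds.

The CV objective is RMSE on the held-out fold, averaged over folds — the
conventional regression default and the primary error statistic of the
evaluation tables. Default budget is 100 evaluations per (model, cultivar,
trait); the desk-scale pipeline default is 30, which the `--full` CLI flag
raises to 100.

## Evaluation statistics and GPI

Six statistics per (cultivar, trait, model, subset): R, R² (= R² of the
correlation), RMSE, RRMSE = 100·RMSE/mean(O), MAE, and
MAPE = (100/n)·Σ|Oᵢ−Pᵢ|/Pᵢ. MAPE divides by the **predicted** value —
unconventional but matching the source convention this package reproduces;
`mape_denominator="observed"` selects the usual form. A zero denominator
makes MAPE missing-with-warning; a zero-variance vector likewise makes
R/R² missing while the error statistics remain defined.

GPI per (cultivar, trait, subset): min-max scale each indicator across the
five models to [0,1]; subtract the per-indicator median (middle order
statistic of five — no interpolation); weight R and R² by −1, the error
indicators by +1; sum over all **six** indicators. A degenerate indicator
(identical across models) contributes zero for every model. Rank 1 is the
highest GPI; ties break lexicographically by model name, with a logged
flag.

Numerical caveat, verified by the packaged fixture check
(`culturopt verify-tables`): GPI is ill-conditioned where an indicator
column barely separates the models — the min-max scale then amplifies
input rounding. Recomputing GPI from the published 2–3-decimal metric
tables reproduces 52 of 60 published values within ±0.02 and the full
ranking (stacking first, everywhere), but a few cells in tightly-spaced
columns deviate by up to ≈1, which is exactly the behavior expected when
the original computation used unrounded metrics.

## NSGA-II and compromise selection

The optimizer is real-coded NSGA-II implemented in this package:
non-dominated sorting (fast variant, cross-checked against an O(n²·m)
brute-force oracle in tests), crowding distance with infinite boundary
values and degenerate objectives contributing zero, binary tournament on
(rank, crowding), SBX crossover (p = 0.9, η = 15), polynomial mutation
(η = 20, per-variable probability 1/2), box bounds equal to the
experimental dose ranges, population 100, 200 generations. ES predictions
are clipped to [0,100] before dominance comparison. The returned rank-1
front is re-verified non-dominated by the package's own sorting primitive
on every run.

The published analysis reports a single dose pair per cultivar without
stating a selection rule. This package's rule — its own convention, named
in every output file — normalizes each objective over the final front to
[0,1] and picks the solution nearest the ideal point (1,1,1,1) in
Euclidean distance; ties break by higher crowding distance, then lowest
(GA₃, ZT). Rank-1 hypervolume is monitored in a toy test; crowding
truncation can trade interior points, so monotonicity is asserted to
within 0.1% of the attained volume.

## Problem sizes

Deterministic checks (GPI recomputation, design arithmetic, dominance
oracles) run in seconds. The end-to-end dose-recovery check runs the full
pipeline — 320 rows per cultivar, tuning budget 30 × 10-fold CV per base
model, stacking, NSGA-II at 100 × 200 — for five seeds per cultivar,
about 75 s per run on one CPU. These are the package's desk-scale
defaults; budget 100 tuning reproduces the same qualitative results with
proportionally longer runtimes.

## Known limitations

- Surrogates are step-like in the dose gap between tested levels (trees
  dominate the ensemble), so optimal-dose coordinates are identified up to
  a plateau: doses between the last two tested levels can be predictively
  indistinguishable, and the reported coordinate sits anywhere on the
  plateau.
- The generator reproduces first and second moments per cell only;
  conclusions about real-data model rankings rest on the published metric
  tables, not on regenerated data.
- On regenerated data the highest-dose corner can dominate all four
  objectives for a cultivar (it does for 'Faroogh'), collapsing the Pareto
  front to a near-point; interior optima reported from the original
  unavailable data are then not recoverable, and predicted survival at the
  compromise saturates at its observed ceiling.
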