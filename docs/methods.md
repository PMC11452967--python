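# Methods

This note documents the models, algorithms, and numerical choices in
`mtgwp`, a toolkit for multi-trait genome-wide prediction with sparse
tabular neural networks.

## Problem setting

Given a genotype matrix of `n` individuals by `p` markers (SNP dosages coded
0/1/2 additively, or 0/1 dominantly) and `k` correlated traits, the goal is
to predict all traits jointly and, where the model supports it, to identify
the markers driving the prediction. All networks consume column-standardized
genotypes and are trained on a multivariate loss: pooled mean squared error
over all `n x k` trait entries for regression, multinomial cross-entropy for
classification.

## Multi-task LassoNet

### Model

```
f(X) = X @ theta + g_W(X)
```

`theta` is a `p x k` matrix of linear skip coefficients (one per marker and
trait). `g_W` is a feed-forward ReLU network whose hidden layers are shared
across traits and whose final layer maps the shared representation to `k`
outputs. Sparsity is imposed through the hierarchy constraint

```
||W_i^(1)||_inf <= nu * sel(theta_i)          for every marker i,
```

where `W_i^(1)` is row `i` of the first hidden layer and `sel` is the
selection functional. A marker can feed the nonlinear pathway only while its
skip row is active, so zeroing `theta_i` removes marker `i` from the entire
network. Two conventions are implemented:

- `elementwise` (default): penalty `sum_t |theta_it|`, selection
  `max_t |theta_it|`;
- `group`: penalty and selection both `||theta_i||_2`.

`nu = 0` collapses the model to the multi-task Lasso; `nu = inf` with
`lambda = 0` is an unconstrained residual network (the plain MLP baseline is
literally this limit, trained by the same routine).

### Hierarchical proximal operator

Each proximal step solves, independently per marker row,

```
min_{theta_i, W_i}  1/2 ||theta_i - b_i||^2 + 1/2 ||W_i - v_i||^2
                    + lambda * pen(theta_i)
s.t.                ||W_i||_inf <= nu * sel(theta_i)
```

The problem is nonconvex jointly, but reduces to a one-dimensional search
over `s = sel(theta_i)`: for fixed `s`, the hidden weights clamp to
`[-nu*s, nu*s]` and the skip coefficients soft-threshold and clip to
`[-s, s]` (raising the cheapest coordinate to `s` when no coordinate reaches
it). The resulting scalar function is strictly convex piecewise-quadratic,
so the exact minimizer is found by sorting the breakpoints (the
soft-thresholded skip magnitudes and the `|v_j|/nu` clamp thresholds),
accumulating suffix sums of slopes and intercepts, and selecting the first
interval whose upper-end derivative is nonnegative. Degenerate zero-width
intervals are skipped explicitly. The operator is vectorized over all `p`
rows; the group convention reduces to the single-coordinate case through the
pseudo-coordinate `||theta_i||_2`. Tests compare it against an independent
grid-plus-polish minimizer on more than a thousand random instances.

### Training protocol

1. **Dense warm start**: `lambda = 0`, full network trained with Adam
   (default; SGD optional), mini-batches, early stopping on validation loss
   with patience, best parameters restored.
2. **Dense-to-sparse path**: starting from the warm start, SGD with momentum
   where every gradient step is followed by the exact hierarchical prox with
   threshold `lambda * learning_rate`; after `epochs_per_step` epochs the
   model is snapshotted and `lambda` grows geometrically
   (`path_multiplier`) until the support is empty.
3. **Selection**: the path point minimizing the validation metric (MSE, or
   `1 - accuracy` for classification); ties break toward smaller support.

The starting `lambda` is chosen automatically from a stationarity argument:
a skip row is eliminated roughly when `lambda` exceeds the row's loss
gradient plus a curvature term (`2/k` for the scaled MSE on standardized
inputs, `0.5/k` for cross-entropy, both upper bounds on the per-row
curvature). `lambda_start` is the 5% quantile of those per-row kill
thresholds, so the path begins where only the weakest rows are at risk; this
accounts for the prox being applied once per mini-batch step rather than
once per path point.

Support size is asserted (not silently enforced) to be non-increasing along
the path in the test suite; the prox itself guarantees feasibility of the
hierarchy constraint after every step, exactly. Monotonicity of the support
is a property of converged path points rather than of the algorithm: because
each lambda step runs only a fixed number of epochs, a gradient update early
in the next step can occasionally re-activate rows the previous prox had
zeroed. At aggressive path settings (large `path_multiplier`, small
`epochs_per_step`) this shows up as transient upticks of a few markers; the
acceptance script reports the largest observed uptick alongside the path
statistics.

### Defaults and rationale

| parameter | default | rationale |
|---|---|---|
| `hidden_sizes` | `(min(100, max(p//3, 8)),)` | single hidden layer scaled to feature count |
| `nu` | 1.0 | balanced linear/nonlinear budget; tune per dataset |
| `path_multiplier` | 1.02 | dense path for accurate selection; raise to 1.1–1.2 for speed |
| `epochs_dense` / `epochs_per_step` | 200 / 10 | warm start does the bulk of the optimization |
| `learning_rate` / `path_learning_rate` | 1e-3 / 5e-3 | Adam dense phase; SGD path phase |
| `momentum` | 0.9 | standard heavy-ball |
| `batch_size` | 64 | small-n genomic cohorts |
| `patience` | 20 | early stopping window (epochs) |

## GANDALF

A stack of Gated Feature Learning Units (GFLUs). Stage `n` selects features
with a learnable sparse mask and updates a `d`-dimensional representation
with GRU-style gates:

```
M_n    = t-softmax(logits_n, t_n)            (feature mask, simplex)
X_n    = M_n * X                             (masked raw input)
z_n    = sigmoid(Wz [phi_{n-1}; X_n])        (update gate)
r_n    = sigmoid(Wr [phi_{n-1}; X_n])        (reset gate)
cand_n = tanh(Wo [r_n * phi_{n-1}; X_n])
phi_n  = (1 - z_n) * phi_{n-1} + z_n * cand_n
```

`phi_0` is a learned linear projection of the stage-1 masked input; the
final representation feeds a small ReLU head with `k` outputs. The
`t-softmax` is a temperature-scaled softmax whose entries below `1e-6` of
the row maximum are clipped to exact zero and renormalized — sparse
selection with the simplex property preserved exactly; the clip support is
held constant with respect to the gradient. Temperatures are per-stage
learnable scalars kept positive through a softplus. Training is end-to-end
Adam with early stopping. Per-stage masks are exported for
interpretability.

Gate contracts verified by tests: `z = 0` leaves the representation
unchanged; `z = 1` replaces it with the candidate; the vectorized training
graph agrees with a sample-wise reference transliteration to 1e-9.

## Synthetic genotype/phenotype generator

Genotypes: haplotypes are drawn from a blockwise Gaussian copula with an
AR(1) latent chain inside each LD block. The latent correlation for each
adjacent pair is calibrated by bisection on the bivariate-normal orthant
probability (Plackett's identity evaluated with 48-node Gauss–Legendre
quadrature) so that the *genotype* correlation matches the requested
`ld_rho`; blocks are independent. Additive coding sums two haplotypes
(0/1/2); dominant coding ORs them (0/1). MAF is sampled uniformly in
`maf_range`; missingness is missing-completely-at-random.

Traits: a set of shared QTLs (pleiotropic, affecting every trait) and
optional trait-specific QTLs receive Gaussian effects on column-standardized
genotypes; optional epistatic product terms can be added. Per-trait noise is
scaled so that the empirical `var(genetic)/var(total)` equals the requested
heritability exactly on the simulated sample (`h2 = 0` yields pure noise,
`h2 = 1` yields a noiseless trait); traits are then z-scored. The generator
returns the full QTL ground truth for recovery experiments.

Scope and limits: the generator produces unrelated individuals (no pedigree
or population structure), bi-allelic markers with block-local LD only, and
Gaussian effect sizes; it is designed for controlled method evaluation, not
for mimicking any particular species' genome.

QC operations: MAF filtering (markers below threshold removed; a filter that
removes everything warns), marginal imputation (missing dosages drawn from
each marker's observed empirical distribution, seeded), liability
thresholding of two continuous traits into four classes and back.

## Evaluation protocol

- **Split**: 70/10/20 train/validation/test; validation and test sizes are
  `floor(frac * n)` and the remainder goes to training, so the partition is
  exact for any `n`.
- **Metrics**: pooled MSE and per-trait-averaged Pearson `r` (regression);
  accuracy and macro one-vs-rest AUC on a 0–100 scale and the K-term
  multiclass Brier score in `[0, 2]` (classification). A uniform K-class
  prediction has Brier `(K-1)/K`.
- **Ensembling**: each model is retrained under 10 seeds; metrics are
  reported as per-seed mean ± standard deviation plus the metric of the
  seed-averaged prediction.
- **Tuning**: Tree-structured Parzen Estimator over log-transformed
  hyperparameters, scored by 5-fold cross-validation on the training
  partition only (stratified for classification). The search stops at the
  iteration budget or when the incumbent has not improved by more than the
  tolerance (default 1e-5) over a 10-trial sliding window. A seeded
  uniform-random engine is available as a fallback.
- **Baselines**: LightGBM (one booster per trait, or a multiclass objective)
  run with `deterministic=True, force_row_wise=True, n_jobs=1` for exact
  reproducibility, and the plain multi-task MLP (the `nu = inf, lambda = 0`
  LassoNet limit).

## Numerical implementation

The package runs on NumPy alone: a small reverse-mode automatic
differentiation engine (float64, broadcasting with gradient unbroadcasting,
matmul/ReLU/tanh/sigmoid/log-softmax/concat primitives, SGD-with-momentum
and Adam optimizers) backs both network models. This keeps the numerics
deterministic, dependency-light, and easily auditable; the gradient of every
primitive is checked against central finite differences in the test suite.
The trade-off is speed — the implementation targets datasets up to a few
thousand samples and markers on one CPU, not GPU-scale cohorts.

## Limitations

- Single-machine, CPU-only; no GPU kernels or data-parallel training.
- The regularization path retrains only `epochs_per_step` epochs per
  `lambda`, so very aggressive `path_multiplier` values can under-converge
  individual path points (the `tol` option adds an inner convergence stop).
- The TPE implementation models hyperparameters with independent univariate
  densities, as in the standard algorithm; strongly interacting
  hyperparameters may need a larger budget.
- The simulator's LD structure is blockwise only and calibrated marginally
  per adjacent pair; long-range LD decay is not modeled.
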