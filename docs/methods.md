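# Methods

## Problem setting and model

Two omics modalities are measured on overlapping sample sets: a source matrix
`X ∈ R^{n×p}` (all samples) and a target matrix `Y ∈ R^{m×q}` observed for a
subset of `m ≤ n` samples. The `k = n − m` samples with no target profile at
all are to be imputed — whole-row missingness, not element-wise gaps. Sample
matching is exact string identity on IDs; both matrices must be non-negative
and finite (expression-scale data, typically `log2(x+1)`-transformed).

The imputer is a conditional Wasserstein GAN. The generator is a fully
connected network `p → 512 → 768 → q` with rectified activations throughout,
including the output layer, so generated expression is non-negative. The
critic is `q → 256 → 128 → 1` with rectified hidden layers and an **identity**
output: a Wasserstein score must be able to go negative, so rectifying the
output node would collapse training. The critic's Lipschitz constraint is the
original weight-clipping recipe — every weight and bias clamped into
`[−0.01, 0.01]` after each optimizer step. Both networks are trained with
RMSprop at learning rate 5·10⁻⁵ (the classic clipped-critic setting),
five critic steps per generator step.

The generator objective, stated as a minimization, is

```
L_G = − mean C(G(X_batch)) + α · L_centroid(G(X_batch)) + β · MSE(Y_obs, G(X_batch)[obs])
```

The adversarial and centroid terms use every row of the batch; the MSE term
only the rows whose target profile is observed. This is the mechanism by which
target-less samples participate in training. For the critic's own loss the
"real" batch is the observed target rows of the current batch and the "fake"
batch is the generated counterparts of those same samples, making it a
translation critic rather than a marginal-distribution critic; generated rows
for missing samples reach the generator's adversarial term but are never
presented to the critic as fakes without a real counterpart.

Defaults: `α = 10⁻²`, `β = 1.0`. The reconstruction term anchors the output
scale, so it carries the larger weight; the centroid term is a regularizer
whose raw magnitude (a squared Frobenius distance between `c × q` matrices)
is much larger than a per-element MSE, and `α = 10⁻²` brings the two
gradients to comparable size at the default problem scale. A small built-in
grid (`α ∈ {0, 10⁻³, 10⁻², 10⁻¹} × β ∈ {0.1, 1}`, selected by validation
MSE) is available via `omicsnmf.training.grid_search` when the defaults are
in doubt. When a large fraction of samples is missing, smaller `α` is
advisable: the centroid reference is then estimated from relatively little
observed data.

Ablation modes of the same trainer double as baselines: `mse_only` disables
the critic and centroid term (a plain feed-forward regression net, the
MSE-only deep baseline), `nmf_only` sets `β = 0` (centroid and adversarial
terms only).

## The centroid-consistency loss

A non-negative factorization `Y ≈ V U` (memberships `V ∈ R^{m×c}`, centroids
`U ∈ R^{c×q}`, default `c = 10`) summarizes the cluster structure of the
target modality. Reference centroids are computed once per training run from
the *training-split* target rows only — never validation rows — and the loss
of a generated batch `Ŷ` is the squared Frobenius distance between the
reference centroids and the batch's centroids.

Three identifiability problems must be resolved before that distance means
anything, and their resolutions define the loss:

1. **Scale ambiguity.** `V U = (V D)(D⁻¹ U)` for any positive diagonal `D`.
   Every decomposition is therefore normalized to unit-maximum membership
   columns, with the scale absorbed into the centroid rows.
2. **Component order.** NMF components are unordered, so the generated
   centroids are aligned to the reference by exact optimal assignment
   (Hungarian algorithm on pairwise squared distances) before subtraction.
   Without matching, the loss is dominated by label-switching noise.
3. **Differentiability.** A multiplicative-update decomposition has no useful
   gradient path. The batch is decomposed on a gradient-detached copy to get
   memberships `V̂`; centroids are then *re-fit* by fixed-membership
   non-negative least squares, `Û = argmin_{U≥0} ‖Ŷ − V̂U‖²_F`, solved
   per-column. With `V̂`, the assignment, and the NNLS active set held fixed
   at the solution, `Û` is linear in `Ŷ` on the free entries, and the
   adjoint of that linear map propagates the centroid-space gradient back to
   the generated batch. The reference centroids are produced by the identical
   refit estimator, so a batch equal to the training data under the same seed
   yields exactly zero loss.

The loss requires batches of at least `c` rows (enforced at configuration
time; a trailing short batch is merged backwards).

## NMF solver

Frobenius-objective Lee–Seung multiplicative updates, seeded, with an
epsilon-guarded denominator. The objective is non-increasing at every
iteration (asserted in tests); iteration stops at `max_iter` (1000 by
default; 2000 for the reference decomposition, 300 for per-batch
decompositions inside training) or when the relative objective decrease
falls below `tol`.

Initialization: centroids are uniform random scaled by `sqrt(mean(Y)/c)`;
memberships are initialized as the projection of each data row onto those
random centroids, rescaled by the best scalar fit. Initializing memberships
from row *content* rather than row *position* makes the entire update
trajectory exactly equivariant under row permutations — shuffling the batch
shuffles the memberships with it and leaves the fitted centroids bit-for-bit
unchanged. With positional random memberships the fitted centroids depend on
sample order through the local optimum reached, which injects pure noise
into the centroid loss. A row of zeros stays at zero membership throughout
(multiplicative updates preserve zeros) and contributes nothing to the fit.

## Training loop and reproducibility

Per epoch, mini-batches (default 64) are drawn from a seeded shuffle of the
training and missing samples. Per batch: five critic updates (each followed
by weight clipping), then one generator update. Validation MSE — generated
versus observed target rows of the validation split — is recorded each epoch,
and the returned model is the best-validation checkpoint, since adversarial
loss curves oscillate and are not usable for model selection. All randomness
(network initialization, shuffling, NMF initializations) derives from one
config seed through named substreams, so runs are bit-reproducible up to
floating-point associativity.

One numerical choice deserves emphasis. The generator's output rectifier is
trained with a **straight-through gradient**: the forward pass is an exact
ReLU (output is truly non-negative, and all-zero weights give all-zero
output), but the backward pass treats the output activation as identity. With
a literal ReLU gradient, any output feature whose pre-activation goes
negative for every sample receives an exactly-zero gradient and can never
recover; on the default benchmark roughly a third of the target features
froze at zero that way, putting a hard floor under the reconstruction error
(training MSE plateaued at ~0.34 where an identity-output network reached
~0.003). The straight-through gradient removes the trap while preserving the
output contract. Hidden layers keep the standard ReLU gradient.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes: `n`
samples (default 400) drawn uniformly from `c_true = 4` latent clusters;
soft memberships = 0.85·one-hot + 0.15·Dirichlet jitter; non-negative
modality-specific centroid matrices with pairwise separation at least
`4·noise_sd`; source `X = V U_x + ε` and target `Y = map(V U_y) + ε` with
zero-truncated Gaussian noise (`noise_sd = 0.05`) and `map` either identity
or a fixed seeded softplus network (a smooth, positive stand-in for
non-linear cross-modality relations). A seeded 25% of samples have their
target row withheld into a ground-truth object the trainer cannot touch.
Binary phenotype labels are a deterministic function of the latent cluster;
survival times are exponential with log-hazard proportional to a latent
cluster risk, with independent uniform censoring (20%).

Default sizes (400 × 60/40, 4 clusters) were chosen so that a full 50-epoch
training run takes well under a minute on one CPU core while leaving enough
samples per cluster for the centroid premise to hold.

What the simulator deliberately does **not** model: library-size or depth
effects, heavy-tailed count noise, batch effects, feature-level sparsity, or
realistic marginal distributions of any particular assay. Passing tests on
this benchmark show the machinery is correct and that the method recovers
shared latent structure under its own assumptions; they say nothing about
performance on any particular real cohort.

## Evaluation conventions

- Random forest: 100 trees, unlimited depth, stratified 5-fold CV, AUC from
  out-of-fold class probabilities, seeded. The "overall" protocol pools
  observed and imputed samples; the "test-set" protocol trains on observed
  samples only and scores imputed samples only.
- Elastic-net Cox: penalty `shrinkage · (r Σ|βᵢ| + (1−r)/2 Σβᵢ²)` with
  `r = 0.5` by default; when no shrinkage is given it is selected by 3-fold
  cross-validated concordance over a logarithmic path. `r = 0` falls back to
  a ridge-penalized Cox fit. At least two observed events are required.
- Prognostic index `PI = βᵀx`; median split with ties assigned to the
  low-risk group in stable input order, so group sizes differ by at most one.
- Log-rank test via the standard two-group chi-squared statistic.
- Cross-split method comparison: two-sided paired Wilcoxon signed-rank per
  method pair across shared splits (at least 10), Holm-corrected; identical
  methods are reported at p = 1.
- k-NN baseline: neighbours in source space, inverse-distance-weighted mean
  of their target rows, uniform weights over exact matches.
- Regression baseline: per-target-feature OLS on the training split, ridge
  fallback when features outnumber training samples, predictions clipped at
  zero.

## Known limitations

- Reconstruction error converges well below naive baselines but not to the
  noise floor: the adversarial and centroid terms deliberately trade
  per-element accuracy for distributional fidelity, and plain regression
  attains lower MSE on linearly-related modalities. This mirrors the method's
  design intent — the claim is better *feature preservation*, not minimal MSE.
- Single source modality only; no multi-source fusion.
- Whole-sample missingness only; element-wise gaps are out of scope.
- Weight clipping is the default critic constraint; a gradient-penalty
  variant is not implemented.
- Exact-string sample matching; assay-specific barcode normalization must
  happen upstream.
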