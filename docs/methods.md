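# Methods

## Problem and model

Single-cell RNA-seq studies that span several experimental batches and
several biological conditions (disease stages, stimulations, time points)
confound three sources of variation: shared cell biology, condition-specific
biology, and technical batch effects. Removing batch effects with standard
integration tools tends to also erase the condition signal. This package
implements a disentangling variational autoencoder that separates the three:
it learns a shared biological embedding used for clustering and
visualization, a condition-specific embedding sharpened by per-condition
batch-normalization branches and a condition classifier, and it attributes
the condition signal back to individual genes.

### Architecture

Input is the preprocessed expression matrix X (n cells x m genes, z-scored)
concatenated with the one-hot batch indicator B (n x b).

- **Shared encoder** — two fully connected layers (m+b -> 512 -> 256) with
  ReLU activations including the output, producing nonnegative shared
  features L. ReLU sparsity makes individual latent features activate on
  subsets of cells.
- **Variational heads** — two pairs of single linear layers map L to
  (mu, log sigma^2) for the biological latent Z_bio (d1 = 16 by default) and
  the condition latent Z_cond (d2 = 8). Variances are parameterized as
  exp(log-variance), guaranteeing positivity. Latents are drawn by
  reparameterization Z = sigma^2 * zeta + mu with zeta ~ N(0, I); the
  variance (rather than standard-deviation) scaling of the noise is the
  model's defining convention, and a `reparam_scale="stddev"` switch selects
  the conventional alternative. In eval mode zeta = 0, so embeddings are the
  posterior means.
- **Condition DSBN** — one batch-normalization branch per condition domain:
  rows of Z_cond belonging to condition c are normalized per feature by that
  domain's statistics, (z - mu_c) / sqrt(sigma_c^2 + eps), eps = 1e-5.
  Training uses current-minibatch per-domain statistics and maintains
  running moments (momentum 0.1); eval uses the running moments. The result
  Z'_cond carries what conditions share; the residual Z_sp = Z_cond - Z'_cond
  carries what is condition-specific. The branches are pure normalizations
  by default — learnable per-domain scale/shift would be absorbed into the
  residual and blur its meaning — with a `dsbn_affine` flag for the affine
  variant.
- **Condition classifier** — Z_sp -> 100 -> 100 -> 100 -> 100 -> C with ReLU
  between hidden layers and log-softmax output, trained with cross-entropy
  so that condition identity is not discarded as batch noise.
- **Decoder** — (Z_bio, Z_cond, B) -> 256 -> 512 -> m, ReLU between hidden
  layers and a linear output (the reconstruction target is signed z-scored
  expression).

### Objective

loss = loss_recon + lambda * loss_KL + mu * loss_cls, with

- loss_recon: sum of squared reconstruction errors over all n x m entries;
- loss_KL: closed-form Gaussian KL of both latent blocks to N(0, I),
  (1/2) sum(mu^2 + sigma^2 - 1 - log sigma^2);
- loss_cls: mean per-cell cross-entropy of the condition classifier;
- lambda = mu = 0.001.

Reconstruction and KL are defined as full-data sums; each minibatch step
scales them by n/batch so the stochastic gradient is an unbiased estimate of
the full-data objective and the printed lambda and mu keep their meaning at
any batch size. The Gaussian observation constant of p(X | Z, B) is absorbed
into the unit weight of the squared error.

## Training

Adam with learning rate 1e-4 for a fixed 50 epochs, no schedule and no early
stopping; two parameter groups (main network, classifier) with identical
settings. Minibatches are shuffled each epoch and drawn across all
conditions jointly; DSBN branches normalize whichever condition subsets are
present and skip absent domains. Classifier gradients flow through the
classifier and (weighted by mu) back into the condition and shared encoders;
an `alternating_cls` flag trains the classifier in a separate step instead.
A single seed drives parameter initialization, shuffling and
reparameterization noise, so single-threaded runs replay bit-identically.

The default minibatch size is 16. This is deliberately small: with the fixed
learning rate and epoch count, the number of Adam steps is what determines
convergence, and on benchmark-sized data (hundreds to a few thousand cells)
batches of 128 leave the network undertrained (k-means on Z_bio recovers
planted types at ARI ~ 0.1, versus ~ 0.99 at batch size 16).

All networks are plain numpy with hand-written reverse-mode (and, for the
decoder, forward-mode) differentiation. The stacks involved are small MLPs,
so this is fast on a single CPU and every gradient path is machine-checked
against central finite differences in the test suite.

## Preprocessing

Four steps, in order, tracked by a stage marker that only moves forward:

1. **Filter** — drop cells expressing fewer than 200 genes and genes
   expressed in zero cells. Both masks are computed on the raw matrix and
   applied in one sweep (no iterative re-filtering).
2. **Library-size normalization** — divide each cell by total/median-total.
3. **log(1+x) and HVG selection** — keep the top 3000 genes by
   Seurat-flavor normalized dispersion; ties break by gene identifier, and
   zero-variance genes are never selected (guarding against binning
   artifacts on small inputs).
4. **z-score** — per gene, zero mean and unit population (1/n) variance;
   zero-variance genes become all-zero columns rather than errors.

Sparse matrices are accepted and densified at the z-score step.

## Condition-specific gene attribution

For each cell of a query condition, five reference cells are sampled from
the union of the other conditions (without replacement when possible;
per-cell RNG substreams are keyed by cell id, making the result invariant to
cell order). The unit-normalized deviation between the query cell's Z_sp and
the mean reference Z_sp represents the movement from the other conditions
toward the query condition. The deviation is mapped to a per-gene score,
averaged over query cells, and genes are ranked descending (ties by
identifier); the top 15 are reported.

Two readings of the embedding-to-gene mapping exist, and the package
implements both:

- **decoder reading (default)** — push the deviation forward through the
  generative half: the score is the first-order response of the
  reconstructed expression when the condition embedding moves along the
  deviation (an exact forward-mode directional derivative). Because the
  decoder is trained to reproduce condition-dependent expression, a positive
  score directly means "the model raises this gene's expression under the
  query condition". In simulation this typically recovers 8-15 of the 15
  reportable planted condition-DE genes per condition; in the tail of
  training seeds a single condition can end up weakly localized in the
  latent space and recover fewer.
- **encoder reading** (`method="encoder"`) — pull the deviation back through
  the recognition half as a vector-Jacobian product of the input -> Z_sp
  map (input saliency; the `gene_gradient` function, finite-difference
  checked). This reading is retained for completeness, but the encoder
  Jacobian of a model trained almost entirely by reconstruction is dominated
  by directions unrelated to condition, and in simulation it essentially
  never ranks planted condition genes into the top 15. That failure is what
  motivated making the decoder reading the default.

During attribution the model runs in eval mode: DSBN running statistics are
constants, so in eval Z_sp is an affine per-feature function of Z_cond with
domain-specific offsets. Those offsets separate conditions "for free" in
Z_sp space — which is why deviations are computed in Z_sp but mapped to
genes through a path that reflects what the model has actually learned
about expression.

## Evaluation metrics

k-means (k = number of cell types, seeded) labels the biological embedding;
agreement with ground truth is scored by ARI and NMI. Silhouette-derived
scores use Euclidean distance on the embedding as-is: CASW = (1 + s_ct)/2
rescales the mean cell-type silhouette (higher = purer clusters), BASW =
1 - (1 + s_batch)/2 rewards batch mixing, ASW is their arithmetic mean and
F1 their harmonic mean (so F1 <= ASW always). Label classes with fewer than
two members contribute a silhouette of zero. The evaluation protocol draws
ten stratified subsamples of 95% of each cell type and reports per-replicate
values with mean and standard deviation; fraction 1 with one replicate is
the no-sampling path for large datasets.

The exact rescaling conventions for BASW/CASW vary across the integration
literature; the ones above are pinned here and all four components are
emitted separately so any other convention can be recomputed downstream.

## Synthetic data

The generator reproduces the structure of the benchmark design used
throughout: 3 conditions (T1-T3) x 2 samples each (the sample id doubles as
the batch label), six cell types of which c1-c3 appear everywhere and c4,
c5, c6 are absent from T1, T2, T3 respectively; 100 cells per present type
per sample (3000 cells) over 4977 genes by default.

Counts are negative binomial (gamma-Poisson) with dispersion alpha = 0.5
(variance mu + alpha mu^2) and log-scale additive structure: a baseline gene
log-mean ~ N(0, 1); per-type marker blocks (5% of genes per type, disjoint,
log-fc 2.0); per-condition DE gene sets (30 genes each, disjoint from
markers and from each other, log-fc 1.5); and per-(gene, batch) shifts
~ N(0, 0.3^2). These effect sizes are the package's calibration of a
"moderate effects" regime: types are clearly separable, batches visibly
shift expression, and condition effects are real but not dominant.

`easy_benchmark` is a 600-cell, 1000-gene preset of the same design (20
cells per type per sample) with strong effects — type log-fc 2.5 with 6%
markers, condition log-fc 2.0 — sized so that a full 50-epoch training run
takes on the order of a minute on one CPU. "Easy" is defined by two
properties the test suite checks: PCA + k-means on the preprocessed counts
already recovers the planted types (ARI >= 0.7) before any integration, and
the full pipeline recovers planted condition-DE genes.

What the generator does not emulate: empirical mean-variance trends fitted
to a real dataset, zero inflation beyond the NB's own zeros, nonlinear
(e.g., cell-type-specific) batch effects, or condition effects restricted
to subsets of cell types. Passing tests therefore demonstrate that the
implementation recovers the structure it models — planted types, additive
batch shifts, global condition-DE — not performance on any particular real
dataset.

## Numerical choices and edge cases

- DSBN eps = 1e-5; running-stat momentum 0.1; population (biased) variance
  in both the batch statistics and the z-score step.
- A condition domain with a single cell in a training minibatch normalizes
  to zero (z - mu_c = 0); domains absent from a minibatch are skipped; at
  eval, running statistics always apply.
- The residual identity Z_sp + Z'_cond = Z_cond is maintained bit-exactly by
  recomposing Z_cond from the two parts after the subtraction (IEEE floats
  do not guarantee (a-b)+b == a).
- Zero-norm attribution deviations are skipped with a log notice; a query
  with no usable cells is an error.
- Checkpoints are HDF5: all weights, DSBN running statistics, the label
  coding tables and the loss history, sufficient to reproduce `transform`
  exactly.

## Known limitations

- The classifier weight mu = 0.001 gives only weak pressure to concentrate
  condition signal in Z_cond; on data where condition effects are subtle the
  attribution degrades gracefully toward noise rather than failing loudly.
- Condition effects are modeled as global (all cell types shifted equally);
  cell-type-restricted condition responses are out of scope of the
  generator and untested.
- The metric suite assumes ground-truth cell-type labels; there is no
  label-free evaluation path.
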