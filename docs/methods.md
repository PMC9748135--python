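# Methods

This note states precisely what `multidec` computes. Notation: `X^r` and
`X^s` are the raw cells × features count matrices of the mRNA and second
(ADT or ATAC gene-activity) modality; `n` cells, `K` clusters.

## Preprocessing (`multidec.data`)

Per modality:

1. Drop features with zero total count.
2. Size factors `s_i = L_i / median(L)` with `L_i` the cell's library size
   (total count). Cells with zero library size are rejected.
3. Normalized input: `log1p(x_ij / s_i)`, then each feature standardized to
   zero mean and unit variance (constant features map to zero columns).
4. Highly variable feature selection (variance of the log-normalized values)
   is applied to mRNA and ATAC (default 2000 features) but not to ADT, which
   is low-dimensional and used in full.

Raw counts are retained: the reconstruction likelihood is evaluated on them,
never on the normalized values. Batch labels, when present, are one-hot
encoded in order of first appearance.

## Network (`multidec.network`)

A single encoder consumes the concatenation of the corrupted normalized
matrices (plus the one-hot batch indicator in conditional mode). Corruption
is additive Gaussian noise, `x + sigma * N(0,1)`, with `sigma = 2.5` for
mRNA and ATAC and `1.5` for ADT. Two decoders map the bottleneck (plus the
batch indicator) back toward each modality. Every hidden layer is
affine → batch-norm → ELU.

Presets:

* **cite** (RNA + ADT): encoder widths {256, 64, 32, 16} (16-d latent), RNA
  decoder {16, 64, 256}, ADT decoder {16, 20}.
* **smage** (RNA + ATAC): encoder {256, 128, 64} (64-d latent), both decoders
  {64, 128, 256}.

Each decoder ends in three affine heads producing the ZINB parameters:

* mean `mu = diag(s) * exp(W_mu h)` (size-factor scaled; the affine output is
  clamped to roughly [-11.5, 13.8] before exponentiation),
* dispersion `theta = exp(W_theta h)` (clamped to [-9.2, 9.2]),
* dropout probability `pi = sigmoid(W_pi h)`.

Evaluation mode (used whenever the latent space is read out) uses clean
inputs and frozen batch-norm running statistics, so embeddings are
deterministic.

## Losses (`multidec.losses`)

**Reconstruction.** The ZINB negative log-likelihood of the raw counts,

```
P(x) = pi * I[x = 0] + (1 - pi) * NB(x | mu, theta),
NB(x | mu, theta) = C(x + theta - 1, x) * (theta/(theta+mu))^theta * (mu/(theta+mu))^x,
```

evaluated entirely in log space via log-gamma, summed over features and
averaged over the cells of the minibatch. One term per modality.

**Self-training KL.** For a minibatch latent matrix `Z`: `Q` is the
row-normalized t-kernel `1 / (1 + ||z_i - z_j||^2)` with zero diagonal; the
target `P` squares `Q`, divides by column sums, and renormalizes rows. The
loss is `KL(P || Q) / n` with `P` treated as a constant (no gradient).

**Deep soft K-means.** With centroids `V`, soft weights
`w_ij ∝ exp(-||z_i - v_j||)` are sharpened by the inflation exponent
(`w^alpha` renormalized, `alpha = 2`) and treated as constants; the loss is
`sum_ij w_ij * tau * ||z_i - v_j|| / n` (Euclidean distance, not squared).

**Total.** `L = L_rna + L_second + gamma * L_cluster + phi * L_KL` with
`gamma = 0.1` for both presets, `phi = 0.001`, `tau = 1` for cite and
`phi = 0.005`, `tau = 0.1` for smage.

Averaging every term over minibatch cells (keeping feature sums) leaves the
relative weights identical to per-cell sums and makes gradient magnitude
independent of batch size.

## Training (`multidec.trainer`)

* **Stage 1 (pretraining).** Adam with AMSGrad, learning rate 0.001, batch
  size 256, default 400 epochs. The first half of the epochs uses
  reconstruction only; the KL term is added afterwards.
* **Stage 2 (clustering).** Centroids are initialized by seeded multi-restart
  K-means (20 restarts) on the pretrained embedding, then optimized jointly
  with all network weights by Adadelta (lr 1.0, rho 0.95) under the total
  loss. After each epoch cells are hard-assigned to the nearest centroid
  (ties to the lowest centroid index); training stops when fewer than 0.1%
  of cells change label, or at the epoch cap.

Unimodal and concatenated-input single-decoder variants expose the same
stream interface and are used for ablation (`mode="rna"`, `"second"`,
`"concat"`).

## Metrics (`multidec.metrics`)

Implemented from contingency tables: pair-counting adjusted Rand index;
normalized mutual information `I / max(H(C), H(G))`; adjusted mutual
information `(I - E[I]) / (max(H) - E[I])` where `E[I]` is the expected
mutual information under the permutation model with fixed marginals
(hypergeometric, computed with log-factorial tables). Degenerate identical
single-cluster partitions score 1.

## Markers (`multidec.markers`)

For source cluster `c`, find a single shared per-feature shift `delta`
(applied to the normalized values of the chosen modality, for all cells of
the cluster) minimizing

```
lambda * mean_i max(0, margin + m_c(z_i + delta) - m_t(z_i + delta)) + ||delta||_1
```

where `m_k` is the log-softmax confidence `-beta * ||z - v_k||` over
centroids and `t` is the target cluster (in one-vs-rest mode, the best other
cluster at each step). Defaults: `lambda = 100`, `margin = 1`, `beta = 1`.
The objective is optimized by proximal gradient descent (ISTA): a gradient
step on the hinge term followed by soft-thresholding, which handles the L1
term exactly and drives irrelevant features to exactly zero.

Features are ranked by `|delta|` descending; rank scores (P down to 1) are
signed by the direction of the size-factor-normalized fold change between the
groups and exported as a two-column `.rnk` file (sorted by signed score) for
preranked gene-set enrichment tools.

## Synthetic data (`multidec.simdata`)

Counts are NB draws with log-mean = feature baseline + group shift +
per-cell within-group noise + log library size (+ per-batch per-feature
shift), with lognormal per-feature dispersion. A logistic dropout then zeroes
entries with probability decreasing in the entry's log-mean. A fraction of
features (`de_fraction`) carries group-specific shifts; optional per-modality
group maps collapse group identities so that a modality resolves only part of
the structure; optional exclusive marker genes receive a fixed +2.0 log shift
in exactly one group. Everything is driven by one seed and is bitwise
reproducible.
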