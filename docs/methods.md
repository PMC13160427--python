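# Methods

## Model

Each cell's expression profile `x_i ∈ R^d` is treated as generated by a
decoder `G` from `k` interpretable categorical factors (batch, experimental
conditions, cell type, ...) plus a residual vector `r_i` capturing variation
not explained by any named factor:

    x_i = G(f_i^1, …, f_i^k, r_i)

One encoder per factor maps `x_i` to logits over that factor's categories; a
separate residual encoder emits `r_i`. Training combines four terms:

- **Classification** — mean cross-entropy between predicted category
  distributions and known labels, over the labeled (cell, factor) pairs only.
- **Entropy regularization** — mean Shannon entropy of the predicted
  distributions over the *unlabeled* pairs, pushing unlabeled predictions
  toward confident, near-one-hot distributions.
- **Residual penalty** — mean squared ℓ2 norm of `r_i`, keeping the residual
  compact so structured signal is absorbed by the factor codes instead.
- **Reconstruction** — MSE on log-normalized data, or negative-binomial
  negative log-likelihood (decoder-emitted mean and per-gene dispersion,
  both softplus-positive) on raw counts.

The total objective is `L_cls + λ1·L_ent + λ2·L_res + λ3·L_rec`. Standard
normal noise (no scale hyperparameter) is added to the residual during
training only, discouraging the decoder from relying on fine residual detail.

### Latent composition

For the decoder input, each factor owns a learned `K × code_dim` embedding
table. A cell's code for a factor is the embedding row of its *true* category
when the label is known, and the softmax-probability-weighted mixture of rows
otherwise. The decoder consumes the concatenation of all factor codes plus
the (noised) residual. Factor blocks are contiguous and ordered as in the
factor specification, so the batch factor occupies the leading columns —
which is what makes block-structured correlation heatmaps meaningful.

Whether the decoder should consume raw softmax vectors or embedded codes is
genuinely open; we chose learned embeddings because they give every factor a
fixed-width, orderable latent block independent of its category count, and
they let label information enter the decoder as a hard one-hot selection.

### Sums vs. means

All four terms are implemented as means over their relevant units rather
than sums over cells, so the default weights are independent of dataset and
batch size. For a fixed label mask this is a positive rescaling with
identical minimizers. Entropies are in nats.

## Defaults and their rationale

| parameter | default | rationale |
|---|---|---|
| encoder hidden sizes | (128, 64) | small MLP; desk-scale CPU training |
| decoder hidden sizes | (64, 128) | mirror of the encoder |
| code_dim | 2 if K ≤ 4 else 8 | binary factors need a thin block; cell types need capacity |
| residual_dim | 10 | roomy enough for unmodeled noise, small enough to regularize |
| λ1 (entropy) | 0.5 | balances terms to the same order of magnitude on the default simulation |
| λ2 (residual) | 0.01 | weak pull; the term only needs to prevent drift |
| λ3 (reconstruction) | 1.0 | reconstruction anchors the representation |
| optimizer | Adam, lr 1e-3, batch 128, 200 epochs | standard for this model size |
| softmax temperature | 1, argmax ties → lowest index | determinism |
| normalization target | median cell depth, then log1p | standard practice |

No entropy-weight annealing is used (constant λ1), and early stopping is off
by default (patience 0) to keep runs deterministic.

The optimization backend is a compact reverse-mode automatic-differentiation
engine (`scdrl.autodiff`) over float64 numpy arrays; its gradients are
verified against central finite differences in the test suite, and Adam is
implemented alongside it.

## Synthetic-data generator

The generator emulates a factorial benchmark: every cell carries one level of
each factor, and counts are negative binomial (Gamma–Poisson) around a
gene-wise mean built from

- a baseline log-mean per gene (N(0, 0.5)),
- a cell-type marker program: shifts of sd 1.0 on a random 20% of genes per type,
- condition effects: log-fold changes of sd 1.0 on a random 10% of genes per level,
- batch effects: multiplicative gene-wise scaling (log-sd 0.3) on **all** genes,

then normalized per cell to a fixed expected depth (2 000 counts by default,
dispersion θ = 1, giving sparsity comparable to real scRNA-seq). Cells of
each type are allocated deterministically and near-evenly across all
batch-by-condition subsets (660 over 8 subsets → four of 82 and four of 83),
so per-type totals are exact and composition carries no randomness.

The default configuration is the published benchmark layout: 500 genes,
2 batches × 2 conditions (Ctrl/Stim) × 2 conditions (Healthy/Severe) ×
16 cell types, 660 cells per type with type 2 rare at 200 cells — 10 100
cells in 8 subsets. A `tiny` configuration (2 000 cells, 200 genes, 8 types,
250 cells each) exists for quick runs; the test suite trains on it.

What the generator does **not** emulate: trajectory/pseudotime structure,
doublets, ambient RNA, zero inflation beyond NB sparsity, gene–gene
correlation beyond the shared factor programs, and per-cell depth variation.
Passing tests therefore demonstrate correct mechanics and recoverable
factorial structure, not performance on arbitrary real data.

## Evaluation suite

- **macro-F1 / ARI** for label recovery (categories absent from both truth
  and prediction are excluded from the macro average; ARI is defined as 1
  when both partitions are a single cluster, where chance correction is
  degenerate).
- **Spearman matrix** between every latent dimension and every factor, both
  against integer-coded labels (reported for comparability, but
  order-dependent for multi-class factors) and as max |ρ| over one-vs-rest
  indicators (the recommended statistic).
- **MIG** with 20-quantile-bin discretization (scale-invariant); per factor
  the gap between the two most informative dimensions, normalized by the
  factor entropy.
- **SAP** with a single-dimension threshold stump scored by balanced
  accuracy, one-vs-rest averaged for multi-class factors.
- **DCI** from a 100-tree random forest per factor (50/50 train/held-out
  split, fixed seed): feature importances give disentanglement and
  completeness via normalized entropies; informativeness is mean held-out
  balanced accuracy. A single-dimension latent has disentanglement 1 by
  definition.
- **Hungarian alignment** at the factor-block level: each factor's latent
  block is scored by its best one-vs-rest |ρ|, and blocks are assigned
  one-to-one to factors to maximize the total; block-level matching is the
  only well-posed one-to-one assignment when factors own multi-dimensional
  blocks.

Because multi-dimension blocks deliberately spread one factor's information
over several coordinates, per-dimension gap metrics (MIG, SAP) are low for a
well-trained block-structured model; they are included for comparability and
are exercised against oracle latents in the tests, while the block-aware
statistics (Spearman block structure, Hungarian) are the ones that reflect
this model's design.

## Numerical and degenerate-input choices

- Missing labels use the sentinel −1, unambiguous with 0-based categories.
- `mask_labels` keeps `round(n·fraction)` cells (round-half-up), all-or-none
  across factors per cell; an optional per-factor mode samples entries
  independently.
- A constant latent dimension has Spearman ρ defined as 0 (logged).
- NB likelihood keeps the `lgamma(x+1)` constant so reported NLLs are honest
  likelihood values (verified against `scipy.stats.nbinom`).
- Entropy uses the `p·log p → 0` limit via `softmax · log_softmax`, which is
  finite for saturated logits.
- Quantile binning collapses duplicate bin edges, so near-discrete dimensions
  are binned by their distinct values.

## Problem sizes in the shipped tests

The unit suite trains on a 600-cell mini design and the acceptance-style
checks on the `tiny` configuration (2 000 cells × 200 genes, 8 types, 60
epochs, three label-masking seeds), where a run takes seconds on one CPU. At
these sizes the binary factors (batch, both conditions) are recovered from 5%
labels at macro-F1 ≥ 0.9, and cell-type recovery rises steeply from 5% to 25%
labels (roughly 0.45 → 0.97 mean macro-F1): 5% of 2 000 cells is only ~12
labeled cells per type, below what the 8-way classifier needs, so the
entropy term sharpens some initially wrong predictions. At the full default
benchmark (10 100 cells, 505 labeled) the same code reaches ≈0.93 cell-type
macro-F1 and ≥0.99 on every binary factor with 5% labels.

## Known limitations

- Identifiability of the residual is not guaranteed: mis-specified or missing
  factors leak structured signal into `r`.
- Semi-supervised entropy sharpening can lock in early mistakes when the
  label budget per category is very small (see above).
- Training is dense single-CPU numpy; atlas-scale data (millions of cells)
  is out of scope.
- No ZINB variant, no KL/adversarial/MMD terms, no amortization over unseen
  categories.
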