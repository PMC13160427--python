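# scdrl

Semi-supervised disentangled representation learning for single-cell RNA-seq.

Single-cell expression profiles mix biological signal (cell type, disease
condition) with technical variation (batch effects) in ways that standard
low-dimensional embeddings entangle. `scdrl` learns a latent space that is
*partitioned by construction*: one contiguous block of coordinates per known
categorical factor — batch, each experimental condition, cell type — plus a
regularized residual block for everything else. It needs labels for only a
small fraction of cells (5% is the working regime) and is aimed at analysts
who want interpretable embeddings, label transfer to unannotated cells, and
batch-aware integration from one model.

## Model

Expression `x_i ∈ R^d` is modeled as `x_i = G(f_i^1, …, f_i^k, r_i)`, where
each `f_i^j` is a categorical factor and `r_i` a residual vector. A dedicated
encoder `E^j` per factor predicts a category distribution
`softmax(E^j(x_i))`; the training objective is

    L = L_cls + λ1·L_ent + λ2·L_res + λ3·L_rec

with cross-entropy `L_cls` on labeled (cell, factor) pairs, Shannon-entropy
regularization `L_ent` on unlabeled pairs (pushing predictions toward
one-hot), a squared-norm penalty `L_res = mean ‖r_i‖²`, and a reconstruction
term `L_rec` (MSE on log-normalized data or negative-binomial likelihood on
raw counts). For the decoder, a factor's code is the learned embedding row of
its true category when the label is known and the probability-weighted
mixture of rows otherwise; standard-normal noise is added to the residual
during training. Defaults: λ1 = 0.5, λ2 = 0.01, λ3 = 1.0 on mean-scaled
terms. See `docs/methods.md` for the full account.

The package also ships a factorial negative-binomial simulator with
ground-truth factor labels and an evaluation suite (macro-F1, ARI, Spearman
factor–dimension structure, MIG, SAP, DCI, Hungarian block matching).

## Worked example

```python
import numpy as np
import scdrl

# 2000 cells x 200 genes, 2 batches x 2x2 conditions x 8 cell types
sim = scdrl.simulate(scdrl.tiny_config(seed=0))
ds = scdrl.normalize(sim.dataset)                  # depth-normalize + log1p
labels = scdrl.mask_labels(sim.truth, 0.05, seed=0)  # keep 5% of labels

result = scdrl.fit(ds, labels, sim.spec,
                   scdrl.ModelConfig(spec=sim.spec, seed=0),
                   scdrl.TrainConfig(epochs=60, seed=0))
preds = scdrl.predict_factors(result.model, ds)

unlabeled = labels.mask[:, 0] == 0
for j, name in enumerate(sim.spec.names):
    f1 = scdrl.macro_f1(sim.truth.labels[unlabeled, j],
                        preds.labels[unlabeled, j])
    print(f"{name:12s} macro-F1 on unlabeled cells: {f1:.3f}")

Z, cmap = scdrl.extract_latent(result.model, ds)
sp = scdrl.spearman_matrix(Z, sim.truth)
lo, hi = cmap["batch"]
jb = sim.spec.names.index("batch")
print(f"batch block |rho| {np.abs(sp.integer_coded[lo:hi, jb]).mean():.2f} "
      f"vs other dims {np.abs(np.delete(sp.integer_coded[:, jb], range(lo, hi))).mean():.2f}")
```

Output:

```
batch        macro-F1 on unlabeled cells: 0.971
condition1   macro-F1 on unlabeled cells: 0.989
condition2   macro-F1 on unlabeled cells: 0.953
cell_type    macro-F1 on unlabeled cells: 0.446
batch block |rho| 0.86 vs other dims 0.04
```

With 5% labels the binary factors are recovered almost perfectly on
never-labeled cells, and the two latent columns owned by the batch factor
carry essentially all batch correlation (0.86 vs 0.04) — the block structure
the model is built for. Cell-type recovery at this reduced scale is
label-starved (about 12 labeled cells per type); it climbs to ≈0.97 at 25%
labels, and at the full 10 100-cell default benchmark reaches ≈0.93 from 5%
labels (`scdrl.default_config()`).

The same pipeline is available from the shell:

```bash
scdrl simulate --preset tiny --out sim/
scdrl train --data sim/expression.h5ad --labels sim/labels.csv \
            --factors sim/factors.yaml --label-fraction 0.05 --seed 0 --out run/
scdrl evaluate --latent run/latent.csv --column-map run/column_map.json \
               --labels sim/labels.csv --factors sim/factors.yaml \
               --predictions run/predictions.csv --out report.json
scdrl benchmark --preset tiny --seeds 3 --out bench/
```

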