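# scdisentangle

Integration of multi-batch, multi-condition single-cell RNA-seq data by
disentangled representation learning, with condition domain adaptation and
gradient-based identification of condition-specific genes.

## The problem

When scRNA-seq samples come from several experimental batches *and* several
biological conditions (disease stages, stimulations, time points), standard
batch-correction tools tend to remove the condition signal together with the
technical noise. `scdisentangle` trains a variational autoencoder that
factors the expression profile of each cell into

- **Z_bio** — a shared biological embedding, cleaned of batch effects, used
  for clustering and visualization;
- **Z_cond** — a condition-specific embedding, sharpened by per-condition
  domain-specific batch normalization (DSBN) and a condition classifier.

The encoder consumes the z-scored expression matrix **X** together with the
one-hot batch indicator **B**; a shared encoder (m+b → 512 → 256, ReLU)
produces shared features from which two variational heads draw
Z_bio ∈ R^{d1} and Z_cond ∈ R^{d2} via reparameterization. One BN branch per
condition domain normalizes Z_cond per feature, (z − μ_c)/√(σ²_c + ε); the
residual **Z_sp = Z_cond − Z′_cond** isolates what is specific to each
condition and feeds a classifier (d2 → 100×4 → C). A decoder maps
(Z_bio, Z_cond, B) back to expression. The objective is

    loss = Σ‖x − x̃‖² + λ · KL(q(Z|X,B) ‖ N(0, I)) + μ · CE(condition)

with λ = μ = 0.001, trained by Adam (lr 1e-4) for 50 epochs.

Condition-specific genes are found by sampling, for every cell of a query
condition, five reference cells from the other conditions, forming the unit
deviation of Z_sp embeddings, mapping that deviation to the gene space
through the trained network, averaging over query cells and reporting the
top 15 genes (see `docs/methods.md` for the two supported readings of that
mapping and why the decoder-side one is the default).

## Worked example

```python
from scdisentangle import (easy_benchmark, preprocess, config_for, fit,
                           transform, kmeans_labels, rank_condition_genes)
from scdisentangle.metrics import ari

ds, truth = easy_benchmark(seed=1)        # 600 cells, 1000 genes, 3 conditions x 2 batches
staged = preprocess(ds)                   # filter -> normalize -> log+HVG -> z-score
state = fit(staged, config_for(staged, seed=1))     # 50 epochs, ~1 min on 1 CPU
bundle = transform(state, staged)

pred = kmeans_labels(bundle.Z_bio, 6, seed=1)
print("ARI vs planted cell types:", round(ari(staged.cell_type, pred), 3))
print("ARI vs batch labels:      ", round(ari(staged.batch, pred), 3))
table = rank_condition_genes(state, staged, "T1", seed=1)
hits = set(table.top_genes) & set(truth.de_genes["T1"])
print("planted T1 genes in top 15:", len(hits))
```

Output:

```
ARI vs planted cell types: 0.987
ARI vs batch labels:       0.024
planted T1 genes in top 15: 15
```

The biological embedding clusters by cell type (ARI ≈ 0.99), not by batch
(ARI ≈ 0.02), and all 15 reported genes for condition T1 are among the 30
planted condition-DE genes.

The same pipeline is available from the shell:

```bash
scdisentangle simulate --easy --seed 1 --out raw.h5ad --truth truth.json
scdisentangle preprocess --in raw.h5ad --out staged.h5ad
scdisentangle train --in staged.h5ad --checkpoint model.h5 --seed 1
scdisentangle integrate --in staged.h5ad --checkpoint model.h5 --out integrated.h5ad
scdisentangle genes --in staged.h5ad --checkpoint model.h5 --out-dir genes/
scdisentangle evaluate --in integrated.h5ad --out report.json
```

`integrate` stores the embeddings under `obsm["X_bio"]` and
`obsm["X_cond_sp"]` so external UMAP tooling can consume them directly.

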