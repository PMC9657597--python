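# linkgnn

Link prediction for bipartite association networks by classifying
**enclosing subgraphs** with a graph neural network.

The motivating problem is computational screening of miRNA–disease
associations: given a curated 0/1 association matrix `Y` (rows miRNAs,
columns diseases), which of the unobserved pairs are likely true
associations?  Instead of relying on externally supplied similarity
matrices, the method learns purely from network topology:

1. For each candidate pair `(m, d)`, extract the *h-hop enclosing
   subgraph* — every node within distance `h` of either center — and
   remove the pair's own edge so the label cannot leak into the input.
2. Label each node by its structural role via **double-radius node
   labeling (DRNL)**: with `d_x`, `d_y` the distances to the two centers
   (each computed with the opposite center masked) and `d = d_x + d_y`,

       f(i) = 1 + min(d_x, d_y) + (d/2)[(d/2) + (d%2) − 1]

   (integer division), centers get label 1, disconnected nodes 0; labels
   are one-hot encoded into the feature matrix `X`.
3. Classify the labeled subgraph with a GNN whose convolution aggregates
   **four propagation operators** at once,

       Z_{t+1} = σ([A·Z_t, A²·Z_t, D⁻¹A·Z_t, D⁻½AD⁻½·Z_t]·W_t),

   `A²` being the key addition for bipartite graphs: it moves information
   directly between same-side nodes (its entries count common neighbors).
   Per-node outputs of all layers are concatenated, **sort pooling** keeps
   the top-k nodes in descending lexicographic order of their embeddings,
   and a small 1-D convolutional read-out produces 2-class log-probabilities
   trained under the negative log-likelihood loss.

Removing one operator at a time reproduces the standard ablation variants
(a: −A, b: −A², c: −D⁻¹A, d: −D⁻½AD⁻½); a single-operator configuration
gives a plain DGCNN-style baseline.

The package bundles a bipartite stochastic-block-model generator, so the
whole pipeline is buildable and testable without any external downloads.

## Worked example

```python
from linkgnn import (SBMSpec, generate_bipartite_sbm, sample_negative_pairs,
                     batch_extract, SubgraphGNNClassifier)

mat = generate_bipartite_sbm(SBMSpec(nm=40, nd=30, n_blocks=2,
                                     p_in=0.4, p_out=0.05, seed=7))
pos = mat.positive_pairs()
neg = sample_negative_pairs(mat, len(pos), seed=7)
subs = batch_extract(mat, pos + neg, h=2)

clf = SubgraphGNNClassifier(epochs=5, seed=0)
clf.fit(subs)
print(f"resolved k = {clf.resolved_k_}")
print("loss:", [f"{x:.4f}" for x in clf.loss_history_])
proba = clf.predict_proba(subs[:3])[:, 1]
print("P(association):", [f"{p:.3f}" for p in proba])
```

prints

```
resolved k = 56
loss: ['0.6716', '0.6197', '0.6095', '0.5981', '0.5938']
P(association): ['0.755', '0.570', '0.689']
```

The training loss falls from near ln 2 (an uninformed 2-class model) as
the classifier learns the planted block structure; the three scores are
the predicted association probabilities of the first three training
pairs.  `BipartiteLinkPredictor` wraps the same pipeline end to end
(`fit(Y)`, `score_pairs`, `rank_candidates("d7")`), and both estimators
follow the scikit-learn contract (`get_params`/`clone`/fitted attributes).

The `linkgnn` command exposes the same pipeline from the shell:

```bash
linkgnn simulate --nm 150 --nd 120 --seed 1 --out data/
linkgnn crossval --edges data/edges.tsv --hop 1,2 --folds 10 --out runs/cv
linkgnn ablate   --edges data/edges.tsv --hop 2 --rounds 1 --out runs/ablate
linkgnn predict  --edges data/edges.tsv --target d7 --out runs/pred
```

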