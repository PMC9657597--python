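# Methods

## Problem and model

Given a bipartite 0/1 association matrix `Y` (side A, e.g. miRNAs, by side
B, e.g. diseases), the task is to score unobserved pairs by how likely they
are to be true associations.  The model treats each candidate pair as a
graph-classification instance: the h-hop enclosing subgraph around the pair
(every node within distance h of either center, in the bipartite graph
induced by `Y`) is extracted, the pair's own edge is deleted, nodes are
labeled by the double-radius hash of their distances to the two centers,
labels are one-hot encoded, and a graph neural network classifies the
labeled subgraph.  Known associations are positives; negatives are drawn
uniformly without replacement from the zero entries, which in curated
databases are *unverified* rather than known-absent — an irreducible source
of label noise the protocol shares with the field's standard setup.

The graph convolution aggregates four propagation operators
simultaneously: the raw adjacency `A`, its square `A²`, the random-walk
normalization `D̃⁻¹Ã`, and the symmetric normalization `D̃⁻½ÃD̃⁻½` (with
`Ã = A + I`).  In a bipartite graph odd powers of `A` connect only
opposite sides, so `A²` is what lets one miRNA see another directly: its
(i, j) entry is the number of common neighbors.  Per layer, the four
propagated feature matrices are concatenated column-wise and mixed by one
trainable weight matrix, followed by a tanh nonlinearity; the per-node
outputs of all layers are concatenated (default widths 32, 32, 1, so a
65-dimensional embedding).  Sort pooling orders nodes descending
lexicographically — last embedding channel first, earlier channels
breaking ties — keeps the top k rows and zero-pads shorter graphs, giving
a fixed k×65 tensor.  The read-out applies a 1-D convolution whose kernel
and stride equal the embedding width (one position per retained node),
max-pooling (2, 2), a second 1-D convolution (kernel 5, 16→32 channels), a
128-unit dense layer, and a 2-class log-softmax trained under the mean
negative log-likelihood.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `h` | 2 | neighborhood radius of the enclosing subgraph |
| `label_cap` | 50 | DRNL labels above the cap share one overflow slot; feature width L = cap + 2 |
| `propagators` | all four | ordered operator subset; ablation removes one, the baseline keeps only `D̃⁻½ÃD̃⁻½` |
| `conv_dims` | (32, 32, 1) | per-layer widths; the final width must be 1 (it is the sort-pooling key) |
| `pooling_k` | 0.6 | fraction → that quantile of training subgraph sizes, clamped to ≥ 10 so the read-out head is valid |
| `epochs` / `batch_size` / `learning_rate` | 50 / 50 / 1e-4 | Adam optimization settings |
| `seed` | — | drives initialization, batching, sampling; fixed seed ⇒ bit-identical runs |

Distances for DRNL are computed on the extracted subgraph with the
opposite center masked (each center's distance field must not shortcut
through the other center); a `distance_scope="full"` option computes them
on the full graph instead.  The classification threshold for
ACC/precision/recall/FPR/MCC is 0.5; AUROC and AUPR are threshold-free
trapezoidal areas, and AUROC coincides with the normalized Mann–Whitney U
statistic (asserted in tests).

## Numerical choices

The network and its backpropagation are implemented directly in
numpy/scipy.  Per minibatch, the per-subgraph operators are stacked
block-diagonally so one sparse product propagates the whole batch; batch
membership is fixed once (seeded) and epochs shuffle batch order, which
keeps the precomputed operator stacks reusable — including across
ablation configurations, which index subsets of the same four operators.
Training runs in single precision by default (exact gradients in whatever
precision is used; a finite-difference check in the test suite verifies
the backward pass), while the functional single-subgraph API and the
operator constructors stay in double precision.  Weights are
Glorot-uniform; zero-degree rows of any inverse degree matrix are set to
zero (isolated nodes arise when masking deletes a pair's only edge);
sort-pooling ties between bit-identical rows are resolved stably, so
permuting a subgraph's non-center nodes cannot change the output.

## The synthetic benchmark and what it can show

The bundled generator plants a bipartite stochastic block model: both
sides are assigned round-robin to `n_blocks` groups and an edge appears
with probability `p_in` within a group and `p_out` across groups.
Round-robin (not random) assignment makes expected counts exact, so
density tests can be tight.  The benchmark configuration is 150×120
nodes, 4 blocks, `p_in = 0.25`, `p_out = 0.02` (≈1 395 positives), with
10% of pooled positives and negatives held out and held-out positives
masked from the adjacency before any extraction.  Heavy evaluations run
the hop sweep over three seeds and the ablation pass on one seed with the
full-model run shared between them — sized to finish in minutes on a
single core.  The untrained-model control averages its metrics over five
random initializations: zero-padding in sort pooling lets subgraph size
leak through any single random projection with a random sign, so one draw
can sit well off 0.5 even though the expectation is 0.5.

Two properties of this generator matter when reading results.  First,
edges are conditionally i.i.d. given block membership, so once a
positive pair's edge is masked its subgraph is distributed exactly like a
within-block negative's: the only recoverable signal is block
co-membership (plus degree noise).  The Bayes-optimal held-out AUROC is
therefore bounded near 0.80 for these proportions — an oracle scoring
true block co-membership achieves 0.832/0.778/0.761 on the three seeded
splits — and the trained hop-2 model's 0.814/0.744/0.759 should be read
against that ceiling, not against 1.0.  Second, block structure is fully
visible from one hop (common neighbors), so larger hops add nodes but
little information here; the hop comparison is a non-inferiority check,
not an expectation of monotone gains.  Real association networks have
heavy-tailed degrees, correlated edges and hierarchical disease
structure, none of which the generator emulates — passing these tests
shows the machinery is correct and can recover planted topology, not that
a particular AUROC will transfer to any real database.

## Known limitations

* Minibatches iterate subgraphs by block-diagonal stacking; there is no
  GPU path and no cross-graph weight amortization beyond that.
* Negative sampling excludes nothing beyond known positives; if a
  candidate list with prior exclusions is needed, pass explicit pairs.
* `A²` of a dense subgraph is itself dense; very dense graphs lose the
  sparsity advantage.
* The one-hot feature space ignores any node attributes; continuous
  features would require widening the input layer.
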