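# gdesce

Grid-density preprocessed deep embedded clustering for single-cell
expression data.

Single-cell RNA-seq clustering has to cope with two confounders at once:
outlier cells that drag cluster boundaries around, and technical batch
effects that can masquerade as biology.  `gdesce` addresses both inside one
pipeline.  A grid-density filter removes isolated cells on a 2-D embedding
before clustering; a stacked autoencoder learns a low-dimensional feature
space; Louvain community detection on a kNN graph of that space fixes the
number of clusters K and the initial centroids; and an iterative
self-training phase refines both the embedding and the centroids under an
entropy-sharpening objective that also discourages batch-driven clusters.
It is aimed at computational biologists who want a self-contained,
dependency-light implementation whose every stage is unit-testable offline.

## Model

Each cell `i` with feature vector `f_i` is soft-assigned to centroid `k_j`
with a Student's-t kernel (degrees of freedom `α`, default 1):

    s_ij = (1 + ‖f_i − k_j‖²/α)⁻¹ / Σ_j (1 + ‖f_i − k_j‖²/α)⁻¹

An auxiliary target distribution sharpens confident assignments while
normalizing per-cluster frequency:

    t_ij ∝ s_ij² / Σ_i s_ij        (rows normalized)

and the loss minimized by minibatch SGD over encoder weights and centroids
(with T frozen and refreshed once per epoch) is the t²-weighted divergence

    L = Σ_i Σ_j t_ij² log( t_ij / s_ij² )

Iteration stops when the fraction of cells whose hard label changed
between epochs falls below a tolerance (default 0.005).

Before any of that, cells are library-size normalized (scale 10 000,
log1p), genes are standardized (within batch when batch labels exist),
highly variable genes are selected by binned dispersion, and the
grid-density filter removes cells in sparse lattice cells of the 2-D PCA
embedding that lie farther than half a grid-cell diagonal from any dense
cell's center.

Evaluation helpers: exact-integer adjusted Rand index, a batch-mixing
metric `KL(p‖q)` between global (`p`) and per-cluster (`q`) batch
proportions, and per-cell label entropy `E_i = −Σ_j P_ij log P_ij`.

## Worked example

```bash
python examples/simulate_and_cluster.py
```

prints (seed 0):

```
simulated 2000 cells x 500 genes, 3 planted populations, 2 batches
clusters found (Louvain init): K = 3
epochs until label changes < 0.005: 1
cells removed by the grid filter: 176
ARI vs planted labels: 1.0000
batch-mixing KL (final): 0.00340
batch-mixing KL (Louvain init): 0.00340
mean label entropy: 0.24986 (0 = fully confident)
```

ARI = 1 means the three planted populations were recovered exactly on the
retained cells; batch KL near zero means no cluster is batch-driven; the
grid filter clipped 176 low-density fringe cells (reported with label −1
so every input cell stays accounted for).  The other examples demonstrate
the outlier filter on a hand-built fixture
(`examples/grid_outlier_filter.py`) and the metrics on closed-form worked
values (`examples/evaluation_metrics.py`).

The same pipeline is available from the shell:

```bash
gdesce simulate --out data/ --seed 0
gdesce run --input data/ --format mtx --labels data/labels.csv --out results/ --seed 0
```

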