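"""End-to-end run: normalize -> HVG -> grid filter -> autoencoder -> cluster.

This is the composition the CLI and the examples drive; every stage is the
corresponding library function, so any piece can be run on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import cluster as _cluster
from . import embedding as _embedding
from . import metrics as _metrics
from . import preprocess as _preprocess
from .config import RunConfig
from .io import CountMatrix

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a run produced, stage by stage."""

    config: RunConfig
    keep_mask: np.ndarray            # per input cell; False = removed outlier
    embedding2d: _preprocess.Embedding2D
    hvg_mask: np.ndarray
    model: _embedding.EncoderModel
    features: _embedding.FeatureMatrix  # retained cells only
    initial_labels: np.ndarray          # Louvain labels on retained cells
    result: _cluster.ClusterResult      # labels over all input cells (-1 = removed)
    report: _metrics.MetricsReport
    initial_batch_kl: Optional[float] = None


def run_pipeline(counts: CountMatrix, cfg: Optional[RunConfig] = None) -> PipelineResult:
    """Run the full clustering pipeline on a raw count matrix.

    Stages: library-size/log normalization and per-gene standardization
    (batch-wise when batch labels are present), HVG selection, a 2-D PCA
    embedding for the grid-density outlier filter, stacked-autoencoder
    pretraining and fine-tuning on the surviving cells, Louvain centroid
    initialization, and the iterative t^2-weighted KL optimization.
    Removed cells carry label -1 in the returned result.
    """
    cfg = cfg or RunConfig()
    by_batch = cfg.by_batch if cfg.by_batch is not None else counts.batch is not None
    norm = _preprocess.normalize_counts(counts, by_batch=by_batch)

    n_top = min(cfg.n_hvg, counts.n_genes)
    hvg_mask = _preprocess.select_hvg(norm, n_top)
    x = norm.values[:, hvg_mask]

    emb2 = _preprocess.pca_embedding(x, seed=cfg.seed)
    if cfg.grid_filter:
        keep = _preprocess.remove_outliers(
            emb2, cfg.grid_cells_per_axis, cfg.density_threshold
        )
    else:
        keep = np.ones(counts.n_cells, dtype=bool)
    xk = x[keep]

    dims = [xk.shape[1]] + cfg.default_encoder_dims(xk.shape[0])
    model = _embedding.pretrain_layerwise(xk, dims, cfg)
    model = _embedding.finetune(model, xk, cfg)
    feats = _embedding.encode(model, xk)

    centroids, init_labels = _cluster.init_centroids_louvain(
        feats, cfg.knn_k, cfg.louvain_resolution, cfg.seed
    )
    res = _cluster.fit(xk, cfg, model=model, init=(centroids, init_labels))

    labels_full = np.full(counts.n_cells, -1, dtype=int)
    labels_full[keep] = res.labels
    result = _cluster.ClusterResult(
        labels=labels_full,
        soft=res.soft,
        centroids=res.centroids,
        loss_trace=res.loss_trace,
        tol_trace=res.tol_trace,
        entropy_trace=res.entropy_trace,
        n_epochs=res.n_epochs,
        cell_ids=list(counts.cell_ids),
    )

    per_cell_e, mean_e = _metrics.label_entropy(res.soft)
    ari = None
    if counts.truth is not None:
        ari = _metrics.adjusted_rand_index(
            np.asarray(counts.truth)[keep], res.labels
        )
    bkl = per_bkl = init_bkl = None
    if counts.batch is not None:
        batch_kept = np.asarray(counts.batch)[keep]
        bkl, per_bkl = _metrics.batch_kl(batch_kept, res.labels)
        init_bkl, _ = _metrics.batch_kl(batch_kept, init_labels)
    report = _metrics.MetricsReport(
        mean_entropy=mean_e,
        per_cell_entropy=per_cell_e,
        ari=ari,
        batch_kl=bkl,
        per_cluster_batch_kl=per_bkl,
        n_cells=counts.n_cells,
        n_outliers_removed=int((~keep).sum()),
        K=result.K,
        n_epochs=res.n_epochs,
    )
    return PipelineResult(
        config=cfg,
        keep_mask=keep,
        embedding2d=emb2,
        hvg_mask=hvg_mask,
        model=model,
        features=feats,
        initial_labels=init_labels,
        result=result,
        report=report,
        initial_batch_kl=init_bkl,
    )
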