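"""Clustering-quality and batch-mixing metrics.

ARI is the chance-corrected pair-counting agreement between two labelings,
computed from the contingency table with exact integer arithmetic.  Batch
mixing is scored as the KL divergence KL(p || q) between the global batch
proportions p and each cluster's batch composition q, aggregated by
cluster-size weighting; 0 means every cluster reproduces the global batch
mix.  Per-cell label entropy E_i = -sum_j P_ij log P_ij quantifies
assignment confidence (natural log throughout).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np

__all__ = ["MetricsReport", "adjusted_rand_index", "batch_kl", "label_entropy"]

Q_FLOOR = 1e-10  # floor for within-cluster batch proportions inside logs


@dataclass
class MetricsReport:
    """Evaluation summary of one clustering run."""

    mean_entropy: float
    per_cell_entropy: np.ndarray
    ari: Optional[float] = None
    batch_kl: Optional[float] = None
    per_cluster_batch_kl: Optional[np.ndarray] = None
    n_cells: int = 0
    n_outliers_removed: int = 0
    K: int = 0
    n_epochs: int = 0

    def to_dict(self) -> dict:
        return {
            "ari": None if self.ari is None else float(self.ari),
            "batch_kl": None if self.batch_kl is None else float(self.batch_kl),
            "per_cluster_batch_kl": (
                None
                if self.per_cluster_batch_kl is None
                else [float(v) for v in self.per_cluster_batch_kl]
            ),
            "mean_entropy": float(self.mean_entropy),
            "n_cells": int(self.n_cells),
            "n_outliers_removed": int(self.n_outliers_removed),
            "K": int(self.K),
            "n_epochs": int(self.n_epochs),
        }


def _exclude_removed(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred_int = pred if np.issubdtype(pred.dtype, np.integer) else None
    keep = np.ones(len(pred), dtype=bool)
    if pred_int is not None:
        keep &= pred != -1
    if np.issubdtype(truth.dtype, np.integer):
        keep &= truth != -1
    return truth[keep], pred[keep]


def adjusted_rand_index(truth, pred) -> float:
    """Exact adjusted Rand index between two labelings.

    Cells labeled -1 in either vector (outliers removed before clustering)
    are excluded pairwise.  Pair counts use exact integer arithmetic via
    the contingency table n_uv with marginals a_u, b_v:

        ARI = (sum C(n_uv,2) - E) / (0.5*(sum C(a_u,2)+sum C(b_v,2)) - E),
        E   = sum C(a_u,2) * sum C(b_v,2) / C(n,2).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("label vectors must have equal length")
    truth, pred = _exclude_removed(truth, pred)
    n = len(truth)
    if n < 2:
        raise ValueError("fewer than 2 cells after excluding removed cells")

    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    U, V = ti.max() + 1, pi.max() + 1
    cont = np.zeros((U, V), dtype=np.int64)
    np.add.at(cont, (ti, pi), 1)

    sum_nij = sum(comb(int(v), 2) for v in cont.ravel())
    sum_a = sum(comb(int(v), 2) for v in cont.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in cont.sum(axis=0))
    total = comb(n, 2)

    # exact integer numerator/denominator (scaled by 2*total) before the
    # single final float division
    numer = 2 * (sum_nij * total - sum_a * sum_b)
    denom = (sum_a + sum_b) * total - 2 * sum_a * sum_b
    if denom == 0:  # both labelings trivial (single cluster each)
        return 1.0
    return numer / denom


def batch_kl(batch, clusters) -> tuple[float, np.ndarray]:
    """Batch-mixing KL divergence, overall and per cluster.

    ``p_b`` is the global proportion of batch b among evaluated cells;
    within each cluster, ``q_b`` is the cluster's batch composition.  Each
    cluster scores KL(p || q) = sum_b p_b log(p_b / q_b) with q floored at
    1e-10, and the overall value is the cluster-size-weighted mean.  Cells
    with cluster label -1 are excluded.  Lower is better-mixed; 0 means
    every cluster mirrors the global batch proportions.
    """
    batch = np.asarray(batch)
    clusters = np.asarray(clusters)
    if batch.shape != clusters.shape:
        raise ValueError("batch and cluster vectors must have equal length")
    if np.issubdtype(clusters.dtype, np.integer):
        keep = clusters != -1
        batch, clusters = batch[keep], clusters[keep]
    if len(batch) == 0:
        raise ValueError("no cells left after excluding removed cells")

    batches, b_idx = np.unique(batch, return_inverse=True)
    B = len(batches)
    p = np.bincount(b_idx, minlength=B) / len(batch)

    labels = np.unique(clusters)
    per_cluster = np.empty(len(labels))
    sizes = np.empty(len(labels))
    for k, lab in enumerate(labels):
        rows = clusters == lab
        sizes[k] = rows.sum()
        if sizes[k] == 0:  # cannot arise from observed labels; guard anyway
            warnings.warn(f"empty cluster {lab!r} skipped", stacklevel=2)
            per_cluster[k] = np.nan
            continue
        q = np.bincount(b_idx[rows], minlength=B) / sizes[k]
        q = np.maximum(q, Q_FLOOR)
        per_cluster[k] = float(np.sum(p * np.log(p / q), where=p > 0))
    valid = ~np.isnan(per_cluster)
    overall = float(np.average(per_cluster[valid], weights=sizes[valid]))
    return overall, per_cluster


def label_entropy(t) -> tuple[np.ndarray, float]:
    """Per-cell Shannon entropy of assignment probabilities and its mean.

    E_i = -sum_j P_ij log P_ij with the 0*log 0 = 0 convention; values lie
    in [0, log K].
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected an n x K probability matrix")
    safe = np.where(t > 0, t, 1.0)
    e = -(t * np.log(safe)).sum(axis=1) + 0.0  # +0.0 normalizes -0.0
    return e, float(e.mean())
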