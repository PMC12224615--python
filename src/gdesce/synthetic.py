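"""Synthetic single-cell count data with planted clusters, batches, outliers.

The generator emulates the regime the clustering method assumes: distinct
cell populations whose expression programs are separated in log space,
batch-specific technical shifts *smaller* than the biological separation,
negative-binomial (Gamma-Poisson) count noise with lognormal library
sizes, and a small fraction of outlier cells whose programs lie far from
every cluster mean so a density filter can isolate them unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import CountMatrix
from .preprocess import Embedding2D

__all__ = ["SyntheticConfig", "generate", "generate_points2d"]


@dataclass
class SyntheticConfig:
    """Parameters of the count generator.

    ``cluster_sep`` is the Euclidean distance between cluster mean
    programs in log-expression space (markers of one cluster are shifted
    up so pairwise center distance equals it exactly); ``batch_shift`` is
    the Euclidean norm of each non-reference batch's additive log-offset
    vector.  ``dispersion`` is the negative-binomial overdispersion phi in
    Var = mu + phi * mu^2.  The validity regime of the method requires
    technical (batch) variation below biological separation, so
    ``batch_shift < cluster_sep`` is enforced by default.
    """

    n_cells: int = 2000
    n_genes: int = 500
    n_clusters: int = 3
    n_batches: int = 2
    cluster_sep: float = 8.0
    batch_shift: float = 3.0
    outlier_frac: float = 0.0
    library_size: int = 10000
    dispersion: float = 0.05
    marker_frac: float = 0.1
    batch_gene_frac: float = 0.2
    library_sigma: float = 0.3
    seed: int = 0
    enforce_regime: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if self.n_clusters < 1 or self.n_batches < 1:
            raise ValueError("n_clusters and n_batches must be positive")
        if self.cluster_sep <= 0:
            raise ValueError("cluster_sep must be positive")
        if self.batch_shift < 0:
            raise ValueError("batch_shift must be nonnegative")
        if not (0.0 <= self.outlier_frac <= 0.2):
            raise ValueError("outlier_frac must lie in [0, 0.2]")
        if self.library_size <= 0 or self.dispersion <= 0:
            raise ValueError("library_size and dispersion must be positive")
        if self.enforce_regime and self.batch_shift >= self.cluster_sep:
            raise ValueError(
                "batch_shift must be smaller than cluster_sep (technical "
                "variation below biological separation); set "
                "enforce_regime=False to override"
            )


OUTLIER_RADIUS_FACTOR = 6.0  # outlier programs sit >= 5x cluster_sep from every mean
MIN_OUTLIER_DISTANCE_FACTOR = 5.0


def generate(cfg: SyntheticConfig) -> tuple[CountMatrix, np.ndarray]:
    """Draw a counts matrix with truth/batch labels and a planted-outlier mask.

    Per-cluster mean log-expression programs are built from a shared
    baseline plus marker-gene shifts sized so cluster centers are exactly
    ``cluster_sep`` apart; each non-reference batch adds a signed offset of
    norm ``batch_shift`` on a random gene subset.  Counts are sampled as
    Gamma-Poisson (negative binomial) around library-size-scaled softmax
    proportions of each cell's log program.  Outlier cells get independent
    random programs at least 5 * cluster_sep from every cluster mean.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes
    Kc = cfg.n_clusters

    base = rng.normal(0.0, 1.0, size=g)

    # disjoint marker sets; per-marker shift delta makes pairwise center
    # distance sqrt(2 m delta^2) equal cluster_sep exactly
    m = max(1, int(round(cfg.marker_frac * g)))
    if Kc * m > g:
        m = max(1, g // Kc)
    marker_pool = rng.permutation(g)[: Kc * m]
    delta = cfg.cluster_sep / np.sqrt(2 * m)
    cluster_means = np.tile(base, (Kc, 1))
    for j in range(Kc):
        cluster_means[j, marker_pool[j * m:(j + 1) * m]] += delta

    # batch offsets: batch 0 is the reference; others get a signed shift of
    # norm batch_shift on a shared random gene subset
    gb = max(1, int(round(cfg.batch_gene_frac * g)))
    batch_genes = rng.permutation(g)[:gb]
    batch_offsets = np.zeros((cfg.n_batches, g))
    if cfg.batch_shift > 0:
        for b in range(1, cfg.n_batches):
            signs = rng.choice([-1.0, 1.0], size=gb)
            batch_offsets[b, batch_genes] = signs * cfg.batch_shift / np.sqrt(gb)

    n_out = int(round(cfg.outlier_frac * n))
    clusters = rng.integers(0, Kc, size=n)
    batches = rng.integers(0, cfg.n_batches, size=n)
    outlier_mask = np.zeros(n, dtype=bool)
    if n_out:
        outlier_mask[rng.choice(n, size=n_out, replace=False)] = True

    log_means = cluster_means[clusters] + batch_offsets[batches]
    if n_out:
        radius = OUTLIER_RADIUS_FACTOR * cfg.cluster_sep
        min_dist = MIN_OUTLIER_DISTANCE_FACTOR * cfg.cluster_sep
        for i in np.nonzero(outlier_mask)[0]:
            while True:
                direction = rng.normal(size=g)
                direction /= np.linalg.norm(direction)
                prog = base + radius * direction
                if np.linalg.norm(cluster_means - prog, axis=1).min() >= min_dist:
                    break
            log_means[i] = prog + batch_offsets[batches[i]]

    # softmax per cell program -> expected expression proportions
    z = log_means - log_means.max(axis=1, keepdims=True)
    props = np.exp(z)
    props /= props.sum(axis=1, keepdims=True)

    mu_lib = np.log(cfg.library_size) - cfg.library_sigma ** 2 / 2
    lib = rng.lognormal(mu_lib, cfg.library_sigma, size=n)
    mu = lib[:, None] * props

    phi = cfg.dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng.poisson(lam).astype(np.int64)

    # a fully zero cell breaks library-size normalization downstream;
    # give it one count at its most expressed gene (vanishingly rare)
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, np.argmax(mu[empty], axis=1)] = 1

    truth = np.array(
        ["outlier" if outlier_mask[i] else f"cluster_{clusters[i]}" for i in range(n)]
    )
    batch = np.array([f"batch_{b}" for b in batches])
    matrix = CountMatrix(
        counts,
        cell_ids=[f"cell_{i:05d}" for i in range(n)],
        gene_ids=[f"gene_{j:04d}" for j in range(g)],
        batch=batch,
        truth=truth,
    )
    return matrix, outlier_mask


def generate_points2d(groups: Sequence[tuple[tuple[float, float], int, float]],
                      stragglers: Sequence[tuple[float, float]] = (),
                      seed: int = 0) -> Embedding2D:
    """Deterministic 2-D point clouds for hand-checkable grid tests.

    ``groups`` is a list of (center, count, spread); each group draws
    ``count`` points uniformly within +/- spread of its center (exactly at
    the center when spread is 0).  ``stragglers`` are appended verbatim, in
    order, after all group points.
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    rng = np.random.default_rng(seed)
    pts = []
    for center, count, spread in groups:
        cx, cy = center
        if spread == 0:
            pts.append(np.tile([cx, cy], (count, 1)).astype(float))
        else:
            pts.append(
                np.column_stack([
                    rng.uniform(cx - spread, cx + spread, size=count),
                    rng.uniform(cy - spread, cy + spread, size=count),
                ])
            )
    if len(stragglers):
        pts.append(np.asarray(stragglers, dtype=float).reshape(-1, 2))
    return Embedding2D(np.vstack(pts), source="synthetic2d")
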