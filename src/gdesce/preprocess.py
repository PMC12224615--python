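"""Normalization, highly-variable-gene selection, and grid-density outlier
removal.

The outlier filter works on a 2-D embedding of the cells (by default the
first two principal components of the HVG-standardized matrix): the plane is
partitioned into a uniform lattice, grid cells holding more points than a
density threshold are *dense*, and points in sparse cells farther than half
a grid-cell diagonal from the nearest dense cell's center are purged.  The
purge is iterated on the survivors until a pass removes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "Embedding2D",
    "GridPartition",
    "normalize_counts",
    "select_hvg",
    "euclidean_distance",
    "build_grid",
    "remove_outliers",
    "pca_embedding",
]

SCALE_FACTOR = 10_000.0  # per-cell library-size scaling before log transform


@dataclass
class NormalizedMatrix:
    """Log-normalized and gene-standardized expression.

    ``log_values`` holds log1p(10^4 * count / cell_total); ``values`` holds
    the same data after per-gene standardization (within each batch when
    ``per_batch``).  The means/stds are kept so standardization is exactly
    invertible per gene.
    """

    values: np.ndarray
    log_values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    batch: Optional[np.ndarray]
    per_batch: bool
    gene_means: np.ndarray  # (n_groups, g)
    gene_stds: np.ndarray   # (n_groups, g); 1.0 where variance was zero
    group_index: np.ndarray  # per-cell row into gene_means/gene_stds
    gene_mask: Optional[np.ndarray] = None

    def unstandardize(self) -> np.ndarray:
        """Invert the per-gene affine standardization, recovering log_values."""
        return self.values * self.gene_stds[self.group_index] + self.gene_means[self.group_index]


def normalize_counts(m: CountMatrix, by_batch: bool = False) -> NormalizedMatrix:
    """Library-size normalize, log-transform, and standardize genes.

    Each cell's counts are divided by the cell's total, scaled by 10 000 and
    log1p-transformed; each gene column is then centred and scaled to unit
    standard deviation — within each batch separately when ``by_batch`` is
    true.  Zero-variance gene columns become all zeros (with a warning)
    rather than NaN.

    Raises
    ------
    ValueError
        If any cell has zero total count (the offending cell is named), or
        if ``by_batch`` is requested without batch labels.
    """
    counts = np.asarray(m.values, dtype=float)
    totals = counts.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"cell {m.cell_ids[zero[0]]!r} has zero total count; "
            f"{zero.size} cell(s) affected"
        )
    log_values = np.log1p(counts / totals[:, None] * SCALE_FACTOR)

    if by_batch:
        if m.batch is None:
            raise ValueError("by_batch=True requires batch labels")
        groups, group_index = np.unique(m.batch, return_inverse=True)
    else:
        groups = np.array([0])
        group_index = np.zeros(m.n_cells, dtype=int)

    g = m.n_genes
    means = np.empty((len(groups), g))
    stds = np.empty((len(groups), g))
    values = np.empty_like(log_values)
    n_flat = 0
    for gi in range(len(groups)):
        rows = group_index == gi
        sub = log_values[rows]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        flat = sd == 0
        n_flat += int(flat.sum())
        sd = np.where(flat, 1.0, sd)
        means[gi], stds[gi] = mu, sd
        values[rows] = (sub - mu) / sd
    if n_flat:
        warnings.warn(
            f"{n_flat} zero-variance gene column(s) set to zeros after centering",
            stacklevel=2,
        )
    return NormalizedMatrix(
        values=values,
        log_values=log_values,
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        batch=None if m.batch is None else np.asarray(m.batch),
        per_batch=by_batch,
        gene_means=means,
        gene_stds=stds,
        group_index=group_index,
    )


def select_hvg(norm, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Mask of the ``n_top`` most variable genes by binned dispersion.

    Per-gene mean and dispersion (variance/mean) are computed on the
    log-normalized scale; genes are placed into ``n_bins`` equal-frequency
    mean bins and dispersions are z-scored within each bin.  The ``n_top``
    genes with the highest normalized dispersion are selected, ties broken
    by gene order.

    ``norm`` may be a :class:`NormalizedMatrix` (its ``log_values`` are
    used) or a plain log-normalized array.
    """
    x = norm.log_values if isinstance(norm, NormalizedMatrix) else np.asarray(norm, float)
    n, g = x.shape
    if n_top > g:
        raise ValueError(f"n_top={n_top} exceeds gene count {g}")
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    # keep bins meaningful on small gene panels: at least ~5 genes per bin
    n_bins = max(1, min(n_bins, g // 5))

    # equal-frequency mean bins; ranks tie-broken by gene order keep binning
    # deterministic under permutations of identical values
    order = np.argsort(mean, kind="stable")
    ranks = np.empty(g, dtype=int)
    ranks[order] = np.arange(g)
    bins = np.minimum((ranks * n_bins) // g, n_bins - 1)

    norm_disp = np.empty(g)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std()
        norm_disp[sel] = 0.0 if sd == 0 else (disp[sel] - mu) / sd

    # top n_top by normalized dispersion, ties broken by gene order:
    # stable sort on negated key keeps earlier genes first among equals
    top = np.argsort(-norm_disp, kind="stable")[:n_top]
    mask = np.zeros(g, dtype=bool)
    mask[top] = True
    return mask


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two 2-D points:
    sqrt((x_a - x_b)^2 + (y_a - y_b)^2)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum()))


@dataclass
class Embedding2D:
    """Per-cell 2-D coordinates used by the grid filter."""

    coords: np.ndarray
    source: str = "external"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def pca_embedding(values: np.ndarray, seed: int = 0) -> Embedding2D:
    """First two principal components of a cells x features matrix."""
    from sklearn.decomposition import PCA

    values = np.asarray(values, float)
    n_comp = min(2, *values.shape)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(values)
    if coords.shape[1] < 2:  # degenerate single-feature input
        coords = np.column_stack([coords[:, 0], np.zeros(len(coords))])
    return Embedding2D(coords, source="pca2")


@dataclass
class GridPartition:
    """Uniform axis-aligned lattice over the bounding box of a point set."""

    cells_per_axis: int
    origin: tuple[float, float]
    cell_size: tuple[float, float]
    counts: np.ndarray       # flattened row-major (ix * cells_per_axis + iy)
    dense_mask: np.ndarray
    point_cells: np.ndarray  # flat grid index per point

    @property
    def p(self) -> int:
        """Total number of grid cells."""
        return self.cells_per_axis ** 2

    @property
    def half_diagonal(self) -> float:
        """Half of a single grid cell's diagonal."""
        dx, dy = self.cell_size
        return 0.5 * float(np.hypot(dx, dy))

    def cell_centers(self, flat_idx: np.ndarray) -> np.ndarray:
        ix, iy = np.divmod(np.asarray(flat_idx), self.cells_per_axis)
        x0, y0 = self.origin
        dx, dy = self.cell_size
        return np.column_stack([x0 + (ix + 0.5) * dx, y0 + (iy + 0.5) * dy])


def build_grid(e: Embedding2D, cells_per_axis: int, d_t: int,
               bounds: Optional[tuple[np.ndarray, np.ndarray]] = None) -> GridPartition:
    """Partition the bounding box of ``e`` into a cells_per_axis^2 lattice.

    Grid cells are half-open except along the max edges, whose points fall
    in the last cell; a cell is dense when its count strictly exceeds
    ``d_t``.  Degenerate inputs (all points identical along an axis) get a
    unit-size cell on that axis.  ``bounds`` fixes the lattice geometry
    ((lo, hi) corner arrays) independently of the points, which the
    iterative outlier purge uses to keep the lattice stable across passes.
    """
    if cells_per_axis < 1:
        raise ValueError("cells_per_axis must be >= 1")
    pts = e.coords
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if bounds is None:
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
    else:
        lo, hi = (np.asarray(b, float) for b in bounds)
    span = hi - lo
    span = np.where(span == 0, 1.0, span)
    size = span / cells_per_axis
    idx2 = np.floor((pts - lo) / size).astype(int)
    idx2 = np.clip(idx2, 0, cells_per_axis - 1)  # max-edge points -> last cell
    flat = idx2[:, 0] * cells_per_axis + idx2[:, 1]
    counts = np.bincount(flat, minlength=cells_per_axis ** 2)
    return GridPartition(
        cells_per_axis=cells_per_axis,
        origin=(float(lo[0]), float(lo[1])),
        cell_size=(float(size[0]), float(size[1])),
        counts=counts,
        dense_mask=counts > d_t,
        point_cells=flat,
    )


def remove_outliers(e: Embedding2D, cells_per_axis: int, d_t: int) -> np.ndarray:
    """Iterative grid-density outlier purge; returns a keep-mask per point.

    On each pass, grid-cell occupancies are recounted over the surviving
    points.  A point in a sparse cell (0 < count <= d_t) is flagged when
    its distance to the center of the nearest dense cell exceeds half of
    one grid cell's diagonal, or when no dense cell exists.  Flagged
    points are removed and the grid is rebuilt on the survivors, until a
    pass removes nothing.  The lattice geometry (origin and cell size) is
    fixed once from the bounding box of the *input* points: the grid
    partitions the embedding plane, and purging points must not re-warp it
    (a shrinking bounding box would make the lattice finer each pass and
    progressively erode cluster margins).

    If a pass would remove *every* surviving point (no cell ever becomes
    dense), the filter backs off: it keeps the current survivors and warns.
    """
    pts = e.coords
    n = pts.shape[0]
    bounds = (pts.min(axis=0), pts.max(axis=0))
    keep = np.ones(n, dtype=bool)
    for _ in range(n):  # each pass removes >= 1 point, so <= n passes
        alive = np.nonzero(keep)[0]
        grid = build_grid(Embedding2D(pts[alive], source=e.source), cells_per_axis,
                          d_t, bounds=bounds)
        sparse_pts = ~grid.dense_mask[grid.point_cells]  # per-alive-point flag
        if not sparse_pts.any():
            break
        dense_cells = np.nonzero(grid.dense_mask)[0]
        if dense_cells.size == 0:
            flagged = np.ones(alive.size, dtype=bool)
        else:
            centers = grid.cell_centers(dense_cells)
            tree = cKDTree(centers)
            dist, _ = tree.query(pts[alive[sparse_pts]])
            flagged = np.zeros(alive.size, dtype=bool)
            flagged[np.nonzero(sparse_pts)[0]] = dist > grid.half_diagonal
        if flagged.all():
            warnings.warn(
                "grid filter would remove every remaining point; "
                "keeping current survivors",
                stacklevel=2,
            )
            break
        if not flagged.any():
            break
        keep[alive[flagged]] = False
    return keep
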