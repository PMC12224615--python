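"""Iterative deep-embedding clustering with a t^2-weighted KL objective.

Cells are soft-assigned to centroids with a Student's-t kernel,

    s_ij = (1 + ||f_i - k_j||^2 / alpha)^-1  /  sum_j (.),

an auxiliary target distribution sharpens the assignment,

    t_ij = (s_ij^2 / sum_i s_ij)  normalized over j,

and the objective

    Loss = sum_i sum_j t_ij^2 * log(t_ij / s_ij^2)

is minimized by minibatch SGD over the encoder weights and the centroids,
with T held fixed and refreshed once per epoch (self-training).  The loop
stops when the fraction of cells whose hard label changed between epochs
drops below a tolerance (default 0.005).

Centroids are initialized by Louvain community detection on a kNN graph of
the bottleneck features, which also fixes the number of clusters K.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RunConfig
from .embedding import EncoderModel, FeatureMatrix

__all__ = [
    "Centroids",
    "ClusterResult",
    "soft_assign",
    "target_distribution",
    "loss",
    "loss_gradients",
    "compute_tolerance",
    "init_centroids_louvain",
    "fit",
]

S_FLOOR = 1e-12  # floor for s inside logarithms


@dataclass
class Centroids:
    """K x d cluster centers in the feature space."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("centroids must be a K x d matrix with K >= 1")
        if not np.isfinite(self.values).all():
            raise ValueError("centroids must be finite")

    @property
    def K(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterResult:
    """Hard labels, soft assignment, centroids and convergence traces.

    ``labels`` uses -1 for cells removed by the outlier filter; ``soft``
    has one row per *retained* cell.  ``entropy_trace`` records the mean
    label entropy of the target distribution at each refresh.
    """

    labels: np.ndarray
    soft: np.ndarray
    centroids: Centroids
    loss_trace: list[float]
    tol_trace: list[float]
    entropy_trace: list[float]
    n_epochs: int
    cell_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i}" for i in range(len(self.labels))]

    @property
    def K(self) -> int:
        return self.centroids.K


def _as_array(x) -> np.ndarray:
    if isinstance(x, (FeatureMatrix, Centroids)):
        return x.values
    return np.asarray(x, dtype=float)


def _sq_dists(f: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, n x K, computed stably."""
    diff = f[:, None, :] - c[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def soft_assign(f, c, alpha: float = 1.0) -> np.ndarray:
    """Student's-t soft assignment of cells to centroids.

    Returns the n x K row-stochastic matrix with
    s_ij proportional to (1 + ||f_i - k_j||^2 / alpha)^-1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    f = _as_array(f)
    c = _as_array(c)
    u = 1.0 / (1.0 + _sq_dists(f, c) / alpha)
    return u / u.sum(axis=1, keepdims=True)


def target_distribution(s) -> np.ndarray:
    """Sharpened auxiliary target: t_ij = (s_ij^2 / sum_i s_ij), row-normalized.

    The division by the per-cluster soft frequency sum_i s_ij balances
    cluster sizes; squaring up-weights confident assignments.
    """
    s = np.asarray(s, dtype=float)
    w = s ** 2 / s.sum(axis=0)
    return w / w.sum(axis=1, keepdims=True)


def loss(s, t) -> float:
    """Objective value sum_ij t_ij^2 * log(t_ij / s_ij^2).

    ``s`` is floored at 1e-12 inside the logarithm; entries with t_ij = 0
    contribute 0 (the x*log x -> 0 convention).
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if s.shape != t.shape:
        raise ValueError("s and t must have the same shape")
    s2 = np.maximum(s, S_FLOOR) ** 2
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = t[pos] ** 2 * np.log(t[pos] / s2[pos])
    return float(out.sum())


def loss_gradients(f, c, t, alpha: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the objective w.r.t. features and centroids.

    With T held fixed (the self-training convention), only the
    -2 * sum t^2 log s part varies.  Writing u_ij = (1+||f_i-k_j||^2/a)^-1
    and T_i = sum_j t_ij^2, the chain rule gives

        dL/df_i  =  (4/a) sum_j u_ij (t_ij^2 - T_i s_ij) (f_i - k_j)
        dL/dk_j  = -(4/a) sum_i u_ij (t_ij^2 - T_i s_ij) (f_i - k_j)

    which is what this function evaluates (vectorized).  Validated against
    central finite differences of :func:`loss`.
    """
    f = _as_array(f)
    c = _as_array(c)
    t = np.asarray(t, dtype=float)
    u = 1.0 / (1.0 + _sq_dists(f, c) / alpha)
    s = u / u.sum(axis=1, keepdims=True)
    T_i = (t ** 2).sum(axis=1)
    A = u * (t ** 2 - T_i[:, None] * s)          # n x K
    coef = 4.0 / alpha
    grad_f = coef * (A.sum(axis=1)[:, None] * f - A @ c)
    grad_c = -coef * (A.T @ f - A.sum(axis=0)[:, None] * c)
    return grad_f, grad_c


def compute_tolerance(curr_labels, prev_labels) -> float:
    """Fraction of cells whose hard label changed between iterations."""
    curr = np.asarray(curr_labels)
    prev = np.asarray(prev_labels)
    if curr.shape != prev.shape:
        raise ValueError("label vectors must have equal length")
    if curr.size == 0:
        raise ValueError("label vectors are empty")
    return float(np.mean(curr != prev))


def init_centroids_louvain(f, knn_k: int = 15, resolution: float = 1.0,
                           seed: int = 0) -> tuple[Centroids, np.ndarray]:
    """Louvain communities on a Euclidean kNN graph fix K and the centroids.

    Builds an undirected k-nearest-neighbor graph on the feature rows, runs
    Louvain (multilevel modularity optimization) at the given resolution,
    and returns per-community feature means as initial centroids together
    with the initial hard labels.
    """
    import igraph
    from sklearn.neighbors import NearestNeighbors

    fv = _as_array(f)
    n = fv.shape[0]
    if n <= knn_k:
        raise ValueError(f"need more cells ({n}) than kNN neighbors ({knn_k})")
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(fv)
    _, idx = nn.kneighbors(fv)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)

    igraph.set_random_number_generator(random.Random(seed))
    membership = np.asarray(
        graph.community_multilevel(resolution=resolution).membership
    )
    K = membership.max() + 1
    if K == 1:
        warnings.warn("Louvain found a single community (K=1)", stacklevel=2)
    centroids = np.vstack([fv[membership == j].mean(axis=0) for j in range(K)])
    return Centroids(centroids), membership


def fit(x, cfg: RunConfig, model: Optional[EncoderModel] = None,
        init: Optional[tuple[Centroids, np.ndarray]] = None,
        cell_ids: Optional[list[str]] = None) -> ClusterResult:
    """Run the iterative clustering optimization.

    Parameters
    ----------
    x
        Either the encoder input matrix (when ``model`` is given) or the
        feature matrix itself; in the latter case the per-cell feature
        vectors are optimized directly as free parameters.
    cfg
        Run configuration (alpha, learning rate, minibatch size, tolerance,
        epoch cap, Louvain settings, seed).
    model
        Pretrained/fine-tuned encoder; gradients of the clustering loss are
        back-propagated through it.
    init
        Optional ``(Centroids, labels)`` to skip Louvain initialization.

    Notes
    -----
    Each epoch refreshes the target distribution T from the current soft
    assignment, takes minibatch SGD steps on the centroids (and encoder
    weights or free features) with T fixed, then evaluates the hard-label
    tolerance against the previous epoch and stops when it falls below
    ``cfg.tol_threshold``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    feats = x.copy() if model is None else None

    def features() -> np.ndarray:
        return feats if model is None else model.encode(x)

    f0 = features()
    if init is None:
        centroids, labels_prev = init_centroids_louvain(
            FeatureMatrix(f0), cfg.knn_k, cfg.louvain_resolution, cfg.seed
        )
    else:
        centroids, labels_prev = init
        labels_prev = np.asarray(labels_prev, dtype=int)
    c = centroids.values.copy()
    K = c.shape[0]
    if n < K:
        raise ValueError(f"fewer cells ({n}) than clusters ({K})")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0])
    lr = cfg.learning_rate
    size = min(cfg.minibatch_size, n)
    loss_trace: list[float] = []
    tol_trace: list[float] = []
    entropy_trace: list[float] = []
    n_epochs = 0

    for epoch in range(1, cfg.max_epochs + 1):
        f = features()
        s = soft_assign(f, c, cfg.alpha)
        t = target_distribution(s)
        full_loss = loss(s, t)
        if not np.isfinite(full_loss):
            raise FloatingPointError(
                f"clustering loss became non-finite at epoch {epoch} "
                f"(lr={lr}, K={K}); try a smaller learning_rate"
            )
        loss_trace.append(full_loss)
        entropy_trace.append(_mean_entropy(t if cfg.entropy_on == "target" else s))

        order = rng.permutation(n)
        for start in range(0, n, size):
            idx = order[start:start + size]
            if model is None:
                fb = feats[idx]
            else:
                fb = model.encode(x[idx], cache=True)
            gf, gc = loss_gradients(fb, c, t[idx], cfg.alpha)
            scale = 1.0 / len(idx)  # per-cell mean keeps lr batch-size free
            c -= lr * scale * gc
            if model is None:
                feats[idx] -= lr * scale * gf
            else:
                model.backprop_encoder(scale * gf, lr, cfg.momentum)

        f = features()
        s = soft_assign(f, c, cfg.alpha)
        labels = np.argmax(s, axis=1)
        tol = compute_tolerance(labels, labels_prev)
        tol_trace.append(tol)
        labels_prev = labels
        n_epochs = epoch
        if tol < cfg.tol_threshold:
            break

    f = features()
    s = soft_assign(f, c, cfg.alpha)
    t = target_distribution(s)
    entropy_trace.append(_mean_entropy(t if cfg.entropy_on == "target" else s))
    return ClusterResult(
        labels=np.argmax(s, axis=1),
        soft=s,
        centroids=Centroids(c),
        loss_trace=loss_trace,
        tol_trace=tol_trace,
        entropy_trace=entropy_trace,
        n_epochs=n_epochs,
        cell_ids=cell_ids,
    )


def _mean_entropy(p: np.ndarray) -> float:
    q = np.where(p > 0, p, 1.0)
    return float(np.mean(-(p * np.log(q)).sum(axis=1)))
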