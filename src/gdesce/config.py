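"""Run-time configuration for the clustering pipeline.

A single :class:`RunConfig` carries every tunable of the pipeline; all
randomness flows from its ``seed`` through one root generator so a run is
reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass
class RunConfig:
    """Parameters of the full grid-filter + deep-embedding clustering run.

    Parameters
    ----------
    n_hvg
        Number of highly variable genes to keep (capped at the gene count).
    grid_cells_per_axis
        Side length of the 2-D lattice used by the outlier filter; the total
        number of grid cells is ``grid_cells_per_axis ** 2``.
    density_threshold
        A grid cell is *dense* when it holds strictly more points than this.
    encoder_dims
        Layer widths of the encoder ending in the bottleneck size, e.g.
        ``[64, 32]``.  ``None`` picks a default from the cell count.
    alpha
        Degrees of freedom of the Student's-t kernel in the soft assignment.
    learning_rate, momentum, minibatch_size
        SGD settings shared by autoencoder training and the clustering phase.
    tol_threshold
        Stop when the fraction of cells whose hard label changed between
        consecutive epochs falls below this value.
    max_epochs
        Hard cap on clustering epochs.
    pretrain_epochs, finetune_epochs
        Epoch budgets for greedy layer-wise pretraining (per layer pair) and
        end-to-end reconstruction fine-tuning.
    louvain_resolution, knn_k
        Community-detection resolution and kNN-graph degree used to pick the
        initial number of clusters and centroids.
    by_batch
        Standardize genes within each batch.  ``None`` means "yes if batch
        labels are present".
    grid_filter
        Disable to skip outlier removal entirely.
    entropy_on
        Which row-stochastic matrix the per-cell label entropy is computed
        from: the sharpened target distribution (``"target"``) or the raw
        soft assignment (``"soft"``).
    """

    n_hvg: int = 3000
    grid_cells_per_axis: int = 50
    density_threshold: int = 3
    encoder_dims: Optional[Sequence[int]] = None
    alpha: float = 1.0
    learning_rate: float = 0.01
    momentum: float = 0.9
    minibatch_size: int = 256
    tol_threshold: float = 0.005
    max_epochs: int = 100
    pretrain_epochs: int = 100
    finetune_epochs: int = 100
    louvain_resolution: float = 1.0
    knn_k: int = 15
    seed: int = 0
    by_batch: Optional[bool] = None
    grid_filter: bool = True
    entropy_on: str = "target"

    def __post_init__(self) -> None:
        if self.n_hvg <= 0:
            raise ValueError("n_hvg must be positive")
        if self.grid_cells_per_axis < 1:
            raise ValueError("grid_cells_per_axis must be >= 1")
        if self.density_threshold < 0:
            raise ValueError("density_threshold must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0.0 < self.tol_threshold < 1.0) and self.tol_threshold != 1.0:
            # tol_threshold = 1.0 is allowed as a degenerate "stop at once"
            raise ValueError("tol_threshold must lie in (0, 1]")
        if self.encoder_dims is not None and len(self.encoder_dims) == 0:
            raise ValueError("encoder_dims must be nonempty when given")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.entropy_on not in ("target", "soft"):
            raise ValueError("entropy_on must be 'target' or 'soft'")

    def default_encoder_dims(self, n_cells: int) -> list[int]:
        """Hidden/bottleneck widths used when ``encoder_dims`` is unset.

        Larger data gets a wider net: [64, 32] for >= 1000 cells, [32, 16]
        below that.
        """
        if self.encoder_dims is not None:
            return list(self.encoder_dims)
        return [64, 32] if n_cells >= 1000 else [32, 16]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["encoder_dims"] is not None:
            d["encoder_dims"] = list(d["encoder_dims"])
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
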