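"""Reading and writing single-cell count matrices and clustering results.

Readers normalize orientation so that cells are always rows, whatever the
on-disk convention (MatrixMarket triplets store genes x cells and are
transposed on load).  Counts are preserved exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["CountMatrix", "read_matrix", "write_result", "write_matrix_mtx"]

#: column names with reserved meaning in CSV inputs
RESERVED_COLUMNS = ("batch", "truth")


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


@dataclass
class CountMatrix:
    """Raw cells x genes UMI counts with identifiers and optional labels.

    ``values`` has one row per cell and one column per gene; entries are
    nonnegative.  ``batch`` and ``truth`` are optional per-cell categorical
    labels (measurement batch, ground-truth cell type).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    batch: Optional[np.ndarray] = None
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if self.values.size and self.values.min() < 0:
            raise ValueError("count matrix contains negative entries")
        for name in ("batch", "truth"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if lab.shape != (n,):
                    raise ValueError(f"{name} labels must have length {n}")
                setattr(self, name, lab)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _find_sidecar(directory: Path, names: Sequence[str]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FormatError(
        f"missing sidecar file in {directory}: looked for {list(names)}"
    )


def _read_mtx(path: Path) -> CountMatrix:
    """MatrixMarket triplet with barcodes.tsv (cells) and features.tsv (genes).

    ``path`` may be the .mtx file itself or a directory containing
    ``matrix.mtx``.  On disk the matrix is genes x cells (10x convention);
    it is transposed so cells are rows.
    """
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FormatError(f"no matrix.mtx in directory {path}")
        path = mtx
    directory = path.parent
    barcodes = _find_sidecar(directory, ("barcodes.tsv",))
    features = _find_sidecar(directory, ("features.tsv", "genes.tsv"))

    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    values = np.asarray(mat).T  # genes x cells on disk -> cells x genes

    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    feat = pd.read_csv(features, sep="\t", header=None)
    gene_ids = feat[0].astype(str).tolist()
    if values.shape != (len(cell_ids), len(gene_ids)):
        raise FormatError(
            f"matrix shape {mat.shape} (genes x cells) inconsistent with "
            f"{len(gene_ids)} features / {len(cell_ids)} barcodes"
        )
    return CountMatrix(values, cell_ids, gene_ids)


def _read_10x_h5(path: Path) -> CountMatrix:
    """10x-style HDF5 (CellRanger v3 layout: a ``matrix`` group holding CSC
    data with shape (genes, cells))."""
    import h5py

    with h5py.File(path, "r") as fh:
        if "matrix" not in fh:
            raise FormatError("expected a 'matrix' group (10x v3 layout)")
        grp = fh["matrix"]
        shape = tuple(grp["shape"][:])  # (genes, cells)
        mat = scipy.sparse.csc_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]), shape=shape
        )
        cell_ids = [b.decode() if isinstance(b, bytes) else str(b) for b in grp["barcodes"][:]]
        feat = grp["features"]["id"] if "features" in grp else grp["genes"]
        gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in feat[:]]
    return CountMatrix(mat.toarray().T, cell_ids, gene_ids)


def _read_csv(path: Path) -> CountMatrix:
    """Dense table: first column cell_id, header row gene ids.  Columns named
    ``batch`` or ``truth`` are pulled out as labels."""
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    batch = truth = None
    if "batch" in df.columns:
        batch = df.pop("batch").to_numpy()
    if "truth" in df.columns:
        truth = df.pop("truth").to_numpy()
    values = df.to_numpy()
    if values.dtype == object:
        raise FormatError(f"non-numeric expression values in {path}")
    return CountMatrix(
        values,
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        batch=batch,
        truth=truth,
    )


_READERS = {"mtx": _read_mtx, "10x-h5": _read_10x_h5, "csv": _read_csv}


def read_matrix(path, format: str) -> CountMatrix:
    """Read a cells x genes count matrix from ``path``.

    Parameters
    ----------
    path
        File (or, for ``mtx``, file or directory) to read.
    format
        One of ``"mtx"``, ``"10x-h5"``, ``"csv"``.

    Returns
    -------
    CountMatrix
        Counts with cells as rows regardless of the on-disk orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_READERS)}")
    return reader(path)


def attach_labels(m: CountMatrix, labels_csv, batch_col: Optional[str] = "batch",
                  truth_col: Optional[str] = "truth") -> CountMatrix:
    """Attach batch/truth labels from a CSV keyed by cell_id (first column)."""
    df = pd.read_csv(labels_csv, index_col=0)
    df.index = df.index.astype(str)
    missing = [c for c in m.cell_ids if c not in df.index]
    if missing:
        raise ValueError(f"label file missing {len(missing)} cell ids (e.g. {missing[0]})")
    df = df.loc[m.cell_ids]
    batch = df[batch_col].to_numpy() if batch_col and batch_col in df.columns else m.batch
    truth = df[truth_col].to_numpy() if truth_col and truth_col in df.columns else m.truth
    return CountMatrix(m.values, m.cell_ids, m.gene_ids, batch=batch, truth=truth)


def write_matrix_mtx(m: CountMatrix, out_dir) -> None:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv
    (genes x cells on disk), plus labels.csv when batch/truth are present."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(np.asarray(m.values).T)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sparse)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", index=False, header=False)
    pd.Series(m.gene_ids).to_csv(out / "features.tsv", index=False, header=False)
    if m.batch is not None or m.truth is not None:
        lab = pd.DataFrame(index=pd.Index(m.cell_ids, name="cell_id"))
        if m.batch is not None:
            lab["batch"] = m.batch
        if m.truth is not None:
            lab["truth"] = m.truth
        lab.to_csv(out / "labels.csv")


def write_result(result, report, out_dir, config=None) -> dict[str, Path]:
    """Write cluster labels, soft assignment probabilities, metrics and config.

    Produces ``labels.csv`` (cell_id, cluster), ``probabilities.csv``
    (cell_id + one column per cluster; NaN rows for cells removed as
    outliers), ``metrics.json`` and ``config.json``.  Returns the paths
    written.  Re-reading labels.csv reproduces the label vector exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    labels = pd.DataFrame(
        {"cell_id": list(result.cell_ids), "cluster": np.asarray(result.labels, dtype=int)}
    )
    paths["labels"] = out / "labels.csv"
    labels.to_csv(paths["labels"], index=False)

    K = result.soft.shape[1] if result.soft.size else result.K
    prob_cols = [f"cluster_{j}" for j in range(K)]
    probs = np.full((len(result.cell_ids), K), np.nan)
    kept = np.asarray(result.labels) >= 0
    if result.soft.size:
        probs[kept] = result.soft
    prob_df = pd.DataFrame(probs, columns=prob_cols)
    prob_df.insert(0, "cell_id", list(result.cell_ids))
    paths["probabilities"] = out / "probabilities.csv"
    prob_df.to_csv(paths["probabilities"], index=False)

    paths["metrics"] = out / "metrics.json"
    with open(paths["metrics"], "w") as fh:
        json.dump(report.to_dict() if report is not None else {}, fh, indent=2)

    paths["config"] = out / "config.json"
    with open(paths["config"], "w") as fh:
        cfg = config.to_dict() if config is not None else {}
        json.dump(cfg, fh, indent=2)
    return paths


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a labels.csv written by :func:`write_result`."""
    df = pd.read_csv(path)
    return df["cell_id"].astype(str).tolist(), df["cluster"].to_numpy(dtype=int)
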