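"""Expression-matrix I/O, quality-control filtering, normalization, and scaling.

The central container is :class:`GeneExpressionMatrix`, a genes x cells matrix
tagged with a ``layer`` describing its processing stage:

``counts``
    raw UMI counts (non-negative integers, sparse-friendly)
``lognorm``
    library-size normalized, ``log(1 + x)``-transformed values
``scaled``
    per-gene z-scores of the lognorm layer, clipped to ``[-clip, +clip]``

Loading supports CellRanger-style Matrix Market directories (``matrix.mtx`` plus
barcode and feature tables) and dense TSV/CSV tables with genes as rows and a
header row of cell barcodes.  Cell-level quality control keeps cells whose
detected-feature count lies strictly inside ``(min_features, max_features)``
and whose mitochondrial-count percentage is strictly below ``max_mito_pct``.
"""

from __future__ import annotations

import glob
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "GeneExpressionMatrix",
    "QCThresholds",
    "FormatError",
    "ConsistencyError",
    "load_expression",
    "filter_cells",
    "lognormalize",
    "scale_genes",
    "read_metadata",
    "write_metadata",
    "write_mtx_dir",
    "write_dense_tsv",
]

LAYERS = ("counts", "lognorm", "scaled")


class FormatError(ValueError):
    """An input file could not be parsed as the declared format."""


class ConsistencyError(ValueError):
    """Companion files (matrix / barcodes / features) disagree on dimensions."""


@dataclass
class GeneExpressionMatrix:
    """A genes x cells expression matrix with unique row/column identifiers.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per matrix row.
    cell_ids
        Unique cell barcodes, one per matrix column.
    values
        ``(n_genes, n_cells)`` numeric matrix; scipy sparse or dense ndarray.
    layer
        One of ``{"counts", "lognorm", "scaled"}``.
    """

    gene_ids: list
    cell_ids: list
    values: object
    layer: str = "counts"

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ConsistencyError("values must be a 2-D genes x cells matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ConsistencyError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids after loading")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.layer == "counts" and self._min_value() < 0:
            raise ValueError("counts layer must be non-negative")

    def _min_value(self) -> float:
        if sp.issparse(self.values):
            return float(self.values.data.min()) if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        """Return values as a dense float ndarray (copy for sparse input)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def cell_totals(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def subset_cells(self, keep: np.ndarray) -> "GeneExpressionMatrix":
        """Column subset by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cells = [self.cell_ids[i] for i in keep]
        return GeneExpressionMatrix(self.gene_ids, cells, self.values[:, keep], self.layer)

    def with_values(self, values, layer: str) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(self.gene_ids, self.cell_ids, values, layer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs; all comparisons in :func:`filter_cells` are strict."""

    min_features: int = 200
    max_features: int = 4500
    max_mito_pct: float = 12.5

    def __post_init__(self):
        if not (0 <= self.min_features < self.max_features):
            raise ValueError("require 0 <= min_features < max_features")
        if not (0 <= self.max_mito_pct <= 100):
            raise ValueError("max_mito_pct must lie in [0, 100]")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_id_column(path: str, column: int = 0) -> list:
    tbl = pd.read_csv(path, sep="\t", header=None, dtype=str)
    col = min(column, tbl.shape[1] - 1)
    return tbl.iloc[:, col].tolist()


def _find_one(directory: str, patterns: list) -> str:
    for pat in patterns:
        hits = sorted(glob.glob(os.path.join(directory, pat)))
        if hits:
            return hits[0]
    raise FormatError(f"no file matching {patterns} in {directory}")


def _collapse_duplicate_genes(genes: list, values) -> tuple:
    """Keep, per symbol, the row with the largest total count (ties: first seen)."""
    if len(set(genes)) == len(genes):
        return genes, values
    totals = np.asarray(values.sum(axis=1)).ravel()
    tbl = pd.DataFrame({"gene": genes, "total": totals})
    # idxmax returns the first occurrence of the maximum, giving the tie rule
    keep = tbl.groupby("gene", sort=False)["total"].idxmax().sort_values()
    idx = keep.to_numpy()
    return [genes[i] for i in idx], values[idx, :]


def load_expression(path: str, fmt: str = "mtx-dir", layer: str = "counts") -> GeneExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        Directory (``mtx-dir``) or file (``tsv``/``csv``) to read.
    fmt
        ``"mtx-dir"`` for a CellRanger-style directory with a Matrix Market
        file plus ``barcodes``/``features`` (or ``genes``) tables; ``"tsv"`` or
        ``"csv"`` for a dense table with gene rows and a cell-id header.
    layer
        Layer tag for the loaded values (default ``"counts"``).

    Duplicate gene symbols are collapsed to the row with the largest total,
    ties broken by first occurrence.
    """
    if fmt == "mtx-dir":
        mtx_path = _find_one(path, ["matrix.mtx", "*.mtx"])
        try:
            mat = mmread(mtx_path)
        except Exception as exc:  # malformed Matrix Market header/body
            raise FormatError(f"could not parse {mtx_path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        barcodes = _read_id_column(_find_one(path, ["barcodes.tsv", "*barcodes*"]))
        feat_path = _find_one(path, ["features.tsv", "genes.tsv", "*features*", "*genes*"])
        genes = _read_id_column(feat_path, column=1)
        if mat.shape[0] != len(genes) or mat.shape[1] != len(barcodes):
            raise ConsistencyError(
                f"matrix is {mat.shape} but feature table has {len(genes)} rows "
                f"and barcode table has {len(barcodes)} rows"
            )
        genes, mat = _collapse_duplicate_genes(genes, mat)
        return GeneExpressionMatrix(genes, barcodes, mat, layer)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            tbl = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
        if tbl.shape[1] == 0:
            raise FormatError(f"{path} has no cell columns")
        genes = [str(g) for g in tbl.index]
        values = tbl.to_numpy(dtype=float)
        genes, values = _collapse_duplicate_genes(genes, values)
        return GeneExpressionMatrix(genes, [str(c) for c in tbl.columns], values, layer)
    raise ValueError(f"unknown format {fmt!r}; expected mtx-dir, tsv or csv")


# ---------------------------------------------------------------------------
# QC / normalization / scaling
# ---------------------------------------------------------------------------

def filter_cells(
    expr: GeneExpressionMatrix,
    mito_prefix: str = "MT-",
    thresholds: QCThresholds | None = None,
) -> GeneExpressionMatrix:
    """Drop low-quality cells from a counts matrix.

    A cell is kept iff its detected-feature count (genes with count > 0) is
    strictly greater than ``min_features`` and strictly less than
    ``max_features``, and its mitochondrial-count percentage is strictly below
    ``max_mito_pct``.  Idempotent; the gene set is unchanged.
    """
    if expr.layer != "counts":
        raise ValueError("filter_cells expects the counts layer")
    thresholds = thresholds or QCThresholds()
    X = expr.values
    if sp.issparse(X):
        detected = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        detected = (X > 0).sum(axis=0)
    totals = expr.cell_totals()
    mito_rows = np.array([g.startswith(mito_prefix) for g in expr.gene_ids])
    if not mito_rows.any():
        warnings.warn(
            f"no genes match mitochondrial prefix {mito_prefix!r}; "
            "mitochondrial percentage treated as 0",
            stacklevel=2,
        )
        mito_pct = np.zeros(expr.n_cells)
    else:
        sub = X[mito_rows, :]
        mito = np.asarray(sub.sum(axis=0)).ravel() if sp.issparse(sub) else sub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = np.where(totals > 0, 100.0 * mito / np.maximum(totals, 1e-300), 0.0)
    keep = (
        (detected > thresholds.min_features)
        & (detected < thresholds.max_features)
        & (mito_pct < thresholds.max_mito_pct)
    )
    return expr.subset_cells(keep)


def lognormalize(expr: GeneExpressionMatrix, scale_factor: float = 1e4) -> GeneExpressionMatrix:
    """Library-size normalize each cell to ``scale_factor`` and apply log1p."""
    if expr.layer != "counts":
        raise ValueError("lognormalize expects the counts layer")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = expr.cell_totals()
    if (totals == 0).any():
        bad = [expr.cell_ids[i] for i in np.flatnonzero(totals == 0)][:5]
        raise ValueError(f"cells with zero total counts (should be filtered): {bad}")
    if sp.issparse(expr.values):
        X = expr.values.astype(float).tocsc()
        X = X @ sp.diags(scale_factor / totals)
        X.data = np.log1p(X.data)
        X = X.tocsr()
    else:
        X = np.log1p(expr.values * (scale_factor / totals))
    return expr.with_values(X, "lognorm")


def scale_genes(expr: GeneExpressionMatrix, clip: float = 10.0) -> GeneExpressionMatrix:
    """Z-score each gene across cells (sample sd, ddof=1) and clip to +-clip.

    Zero-variance genes (including the single-cell edge case) map to all-zero
    rows.  Output is dense.
    """
    if expr.layer != "lognorm":
        raise ValueError("scale_genes expects the lognorm layer")
    if clip <= 0:
        raise ValueError("clip must be positive")
    X = expr.dense()
    mean = X.mean(axis=1, keepdims=True)
    if expr.n_cells > 1:
        sd = X.std(axis=1, ddof=1, keepdims=True)
    else:
        sd = np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    np.clip(Z, -clip, clip, out=Z)
    return expr.with_values(Z, "scaled")


# ---------------------------------------------------------------------------
# metadata and writers
# ---------------------------------------------------------------------------

def read_metadata(path: str) -> pd.DataFrame:
    """Read a per-cell metadata TSV; requires a ``cell_id`` column."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise FormatError(f"{path} lacks the required cell_id column")
    if meta["cell_id"].duplicated().any():
        raise ConsistencyError("metadata contains duplicate cell_id rows")
    return meta


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_dense_tsv(expr: GeneExpressionMatrix, path: str) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def write_mtx_dir(expr: GeneExpressionMatrix, directory: str) -> None:
    """Write a CellRanger-style directory: matrix.mtx, features.tsv, barcodes.tsv."""
    os.makedirs(directory, exist_ok=True)
    values = expr.values if sp.issparse(expr.values) else sp.csr_matrix(expr.values)
    mmwrite(os.path.join(directory, "matrix.mtx"), values.tocoo())
    feat = pd.DataFrame({"id": expr.gene_ids, "symbol": expr.gene_ids})
    feat.to_csv(os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(expr.cell_ids).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )
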