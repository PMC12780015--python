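"""Signature-versus-cell connectivity scoring and derived structure.

Connectivity is the Spearman rank correlation between a directional
signature's scores and one cell's scaled expression, restricted to the
signature genes present in the matrix.  Positive connectivity means the
cell's expression is concordant with the perturbation response (a predicted
*resistant* cell); negative means discordant (predicted *sensitive*).

From the signatures x cells connectivity matrix this module derives
drug-drug Pearson similarity, mechanism-of-action networks by similarity
threshold, Ward clusterings of cells in connectivity space, and per-state
mean-connectivity summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .io_preprocess import GeneExpressionMatrix
from .signatures import DirectionalSignature

__all__ = [
    "score_connectivity",
    "drug_similarity",
    "moa_network",
    "cluster_cells",
    "state_mean_connectivity",
    "ClusterModel",
    "read_connectivity_tsv",
    "write_connectivity_tsv",
]


def score_connectivity(
    expr: GeneExpressionMatrix,
    signatures: list,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Spearman connectivity of every signature with every cell.

    Returns a signatures x cells DataFrame of rank correlations in [-1, 1].
    Ties get average ranks.  A signature sharing fewer than ``min_overlap``
    genes with the matrix yields an all-missing row (with a warning); a cell
    whose expression is constant over the signature genes yields NaN for that
    pair.
    """
    if expr.layer != "scaled":
        raise ValueError("score_connectivity expects the scaled layer")
    X = expr.dense()
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("signature names must be unique")
    out = np.full((len(signatures), expr.n_cells), np.nan)
    for si, sig in enumerate(signatures):
        present = [g for g in sig.genes if g in gene_index]
        if len(present) < max(min_overlap, 2):
            warnings.warn(
                f"signature {sig.name!r} shares {len(present)} genes with the matrix "
                f"(< {min_overlap}); row left missing",
                stacklevel=2,
            )
            continue
        rows = [gene_index[g] for g in present]
        r_sig = rankdata(sig.scores.loc[present].to_numpy())
        r_cells = rankdata(X[rows, :], axis=0)
        a = r_sig - r_sig.mean()
        b = r_cells - r_cells.mean(axis=0, keepdims=True)
        an = np.sqrt((a**2).sum())
        bn = np.sqrt((b**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (a @ b) / (an * bn)
        rho[bn == 0] = np.nan
        if an == 0:
            rho[:] = np.nan
        out[si] = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame(out, index=names, columns=expr.cell_ids)


def drug_similarity(conn: pd.DataFrame, cell_subset: list | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of signatures over their connectivity vectors.

    Missing connectivity values are excluded pairwise.  Constant rows give
    missing correlations (including their own diagonal entry).
    """
    sub = conn if cell_subset is None else conn.loc[:, list(cell_subset)]
    if sub.shape[1] < 3:
        raise ValueError("drug_similarity needs at least 3 cells")
    sim = sub.T.corr(min_periods=2)
    variable = sub.std(axis=1, ddof=0) > 0
    for sig in sim.index:
        sim.loc[sig, sig] = 1.0 if variable.get(sig, False) else np.nan
    return sim


def moa_network(sim: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Undirected edge list (source, target, weight) for similarities > threshold.

    Each unordered pair appears once; self-edges and missing similarities are
    skipped.  The default threshold 0.7 flags shared-mechanism drug pairs.
    """
    if sim.shape[0] != sim.shape[1] or list(sim.index) != list(sim.columns):
        raise ValueError("similarity matrix must be square with matching labels")
    rows = []
    ids = list(sim.index)
    vals = sim.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            w = vals[i, j]
            if np.isfinite(w) and w > threshold:
                rows.append((ids[i], ids[j], float(w)))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


@dataclass
class ClusterModel:
    """Ward clusterings of cells in connectivity-correlation space.

    ``assignments[k]`` holds integer labels (1..k) per cell; ``wss[k]`` the
    within-cluster sum of squares in the coordinate space the distances were
    computed in (the rows of the cell-cell Spearman correlation matrix).
    """

    cell_ids: list
    assignments: dict
    wss: dict
    linkage_method: str = "ward"

    def elbow_k(self) -> int:
        """k with the largest relative WSS drop from its predecessor."""
        ks = sorted(self.wss)
        best_k, best_drop = ks[0], -np.inf
        for prev, k in zip(ks, ks[1:]):
            if self.wss[prev] <= 0:
                continue
            drop = (self.wss[prev] - self.wss[k]) / self.wss[prev]
            if drop > best_drop:
                best_k, best_drop = k, drop
        return best_k


def cluster_cells(
    conn: pd.DataFrame,
    signature_subset: list | None = None,
    k_range: range = range(2, 13),
) -> ClusterModel:
    """Ward clustering of cells on their connectivity vectors.

    Pipeline: pairwise Spearman correlation among cells (over the selected
    signatures) -> Euclidean distance on the rows of that correlation matrix
    -> Ward agglomeration -> assignments and WSS for each k in ``k_range``.
    Cells with missing connectivity are dropped with a warning.
    """
    sub = conn if signature_subset is None else conn.loc[list(signature_subset)]
    ok = ~sub.isna().any(axis=0)
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} cells with missing connectivity", stacklevel=2)
    sub = sub.loc[:, ok]
    cells = list(sub.columns)
    n = len(cells)
    if max(k_range) > n:
        raise ValueError(f"k up to {max(k_range)} requested but only {n} cells")
    F = sub.to_numpy().T  # cells x signatures
    R = rankdata(F, axis=1)
    sds = R.std(axis=1)
    if (sds == 0).any():
        warnings.warn("cells with constant connectivity vectors; correlations set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(R)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    Z = linkage(pdist(C, metric="euclidean"), method="ward")
    assignments, wss = {}, {}
    # k = 1 (total variance) anchors the elbow statistic even when not requested
    ks = sorted({1} | set(k_range))
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        total = 0.0
        for lab in np.unique(labels):
            pts = C[labels == lab]
            total += float(((pts - pts.mean(axis=0)) ** 2).sum())
        assignments[k] = labels
        wss[k] = total
    return ClusterModel(cells, assignments, wss)


def state_mean_connectivity(
    conn: pd.DataFrame,
    meta: pd.DataFrame,
    state_column: str,
    scale: bool = True,
) -> pd.DataFrame:
    """Per-state mean connectivity, optionally z-scaled per signature.

    Rows are states (>= 1 cell each; empty states drop out), columns are
    signatures.  With ``scale=True`` each signature column is centered and
    divided by its sample sd across states; zero-sd columns report 0.
    """
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    cells = [c for c in conn.columns if c in meta.index]
    states = meta.loc[cells, state_column]
    if states.nunique() < 2:
        raise ValueError("state_mean_connectivity needs at least 2 states")
    means = (
        conn.loc[:, cells]
        .T.groupby(states, sort=True)
        .mean()
    )  # states x signatures
    if not scale:
        return means
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    scaled = (means - mu).div(sd.where(sd > 0, 1.0), axis=1)
    scaled.loc[:, sd <= 0] = 0.0
    return scaled


def read_connectivity_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_connectivity_tsv(conn: pd.DataFrame, path: str) -> None:
    conn.to_csv(path, sep="\t", index_label="signature")
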