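"""Per-cell gene-set scoring, predominant-state assignment, and hierarchy coordinates.

Cells are scored against gene-set collections (e.g. the four glioblastoma
meta-modules AC-, MES-, NPC-, OPC-like) with a rank-based single-sample
statistic: rank all genes by scaled expression within the cell and report the
normalized mean rank of the set genes,

    score = (mean_rank(set) - (n + 1) / 2) / n,

which lies in (-0.5, 0.5) and is invariant to any strictly monotone transform
of the cell's expression.  Paired sub-modules (NPC1/NPC2, MES1/MES2) are
collapsed by averaging before the predominant state is assigned by argmax.
A two-dimensional hierarchy embedding places progenitor-like states on top
(y > 0) and differentiated-like states below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_preprocess import GeneExpressionMatrix

__all__ = [
    "StateScores",
    "singscore_cells",
    "collapse_and_assign",
    "hierarchy_coordinates",
    "module_score",
]


@dataclass
class StateScores:
    """Cells x states enrichment scores with optional assignment and coordinates."""

    scores: pd.DataFrame
    assigned: pd.Series | None = None
    coords: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        if self.assigned is not None:
            out["assigned_state"] = self.assigned
        if self.coords is not None:
            out[["x", "y"]] = self.coords
        return out


def singscore_cells(
    expr: GeneExpressionMatrix,
    sets: dict,
    min_genes: int = 5,
) -> StateScores:
    """Rank-based single-sample enrichment of each gene set in each cell.

    Sets sharing fewer than ``min_genes`` genes with the matrix are dropped
    with a warning.  Higher scores mean the set genes rank higher in the
    cell's scaled expression.
    """
    if expr.layer != "scaled":
        raise ValueError("singscore_cells expects the scaled layer")
    X = expr.dense()
    n = expr.n_genes
    ranks = rankdata(X, axis=0)  # ascending: higher expression -> higher rank
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    cols = {}
    for name, genes in sets.items():
        rows = [gene_index[g] for g in genes if g in gene_index]
        if len(rows) < min_genes:
            warnings.warn(
                f"gene set {name!r} matches {len(rows)} genes (< {min_genes}); dropped",
                stacklevel=2,
            )
            continue
        cols[name] = (ranks[rows, :].mean(axis=0) - (n + 1) / 2.0) / n
    if not cols:
        raise ValueError("no gene set shares enough genes with the matrix")
    return StateScores(pd.DataFrame(cols, index=expr.cell_ids))


def collapse_and_assign(scores: StateScores, pairing: dict | None = None) -> StateScores:
    """Average paired score columns and assign each cell its argmax state.

    ``pairing`` maps a collapsed name to the list of columns to average, e.g.
    ``{"NPC": ["NPC1", "NPC2"]}``.  Non-paired columns pass through.  Ties on
    the maximum go to the first state in alphabetical order.
    """
    tbl = scores.scores.copy()
    pairing = pairing or {}
    for new, members in pairing.items():
        missing = [m for m in members if m not in tbl.columns]
        if missing:
            raise ValueError(f"pairing for {new!r} references unknown columns {missing}")
        tbl[new] = tbl[members].mean(axis=1)
        tbl = tbl.drop(columns=[m for m in members if m != new])
    tbl = tbl[sorted(tbl.columns)]  # alphabetical order fixes argmax tie-breaks
    assigned = tbl.idxmax(axis=1)
    return StateScores(tbl, assigned=assigned)


def hierarchy_coordinates(
    scores: StateScores,
    upper_pair: tuple = ("OPC", "NPC"),
    lower_pair: tuple = ("AC", "MES"),
) -> pd.DataFrame:
    """Two-dimensional hierarchy embedding of collapsed state scores.

    ``y = max(upper) - max(lower)``; when y > 0 the cell sits in the upper
    (progenitor-like) half and ``x = upper[0] - upper[1]`` (positive toward
    ``upper[0]``), otherwise ``x = lower[0] - lower[1]`` (positive toward
    ``lower[0]``).  Deterministic for fixed input.
    """
    tbl = scores.scores
    needed = list(upper_pair) + list(lower_pair)
    missing = [s for s in needed if s not in tbl.columns]
    if missing:
        raise ValueError(f"hierarchy_coordinates needs collapsed columns {missing}")
    up = tbl[list(upper_pair)].max(axis=1)
    lo = tbl[list(lower_pair)].max(axis=1)
    y = up - lo
    x_upper = tbl[upper_pair[0]] - tbl[upper_pair[1]]
    x_lower = tbl[lower_pair[0]] - tbl[lower_pair[1]]
    x = x_upper.where(y > 0, x_lower)
    coords = pd.DataFrame({"x": x, "y": y}, index=tbl.index)
    scores.coords = coords
    return coords


def module_score(
    expr: GeneExpressionMatrix,
    gene_set: list,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-matched module score per cell (AddModuleScore-style).

    Genes are binned into ``n_bins`` equal-size bins by average lognorm
    expression; for each set gene, ``n_ctrl`` control genes are drawn
    (seeded) from the same bin excluding the set itself, and the score is the
    mean set-gene expression minus the mean control-gene expression per cell.
    """
    if expr.layer != "lognorm":
        raise ValueError("module_score expects the lognorm layer")
    if n_bins > expr.n_genes:
        raise ValueError("n_bins exceeds the number of genes")
    X = expr.dense()
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = [gene_index[g] for g in gene_set if g in gene_index]
    if len(rows) < 2:
        raise ValueError("gene set shares fewer than 2 genes with the matrix")
    avg = X.mean(axis=1)
    order = pd.Series(avg).rank(method="first")
    bins = pd.qcut(order, n_bins, labels=False).to_numpy()
    rng = np.random.default_rng(seed)
    in_set = np.zeros(expr.n_genes, dtype=bool)
    in_set[rows] = True
    ctrl_rows: list[int] = []
    for r in rows:
        pool = np.flatnonzero((bins == bins[r]) & ~in_set)
        if pool.size == 0:  # bin holds only set genes; fall back to the whole bin
            pool = np.flatnonzero(bins == bins[r])
        replace = pool.size < n_ctrl
        ctrl_rows.extend(rng.choice(pool, size=n_ctrl, replace=replace).tolist())
    set_mean = X[rows, :].mean(axis=0)
    ctrl_mean = X[ctrl_rows, :].mean(axis=0)
    return pd.Series(set_mean - ctrl_mean, index=expr.cell_ids)
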