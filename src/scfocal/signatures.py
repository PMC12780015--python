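"""Directional drug signatures and per-state pseudo-bulk disease signatures.

A *directional signature* maps genes to signed scores: positive scores mark
genes a perturbation pushes up, negative scores genes it pushes down.  Three
constructors are provided:

* :func:`build_consensus_signature` — a cross-context consensus (the
  transcriptional-consensus-signature idea: keep genes whose direction agrees
  across most measured contexts and whose median magnitude is large enough).
* :func:`build_response_signature` — from a bulk differential-expression
  table, keeping genes beyond ``mean + sd_mult * sd`` of the logFC
  distribution at an adjusted-p cutoff.
* :func:`build_disease_signatures` — per-tumor-state pseudo-bulk
  differential expression against a pooled normal-cell reference (log2 ratio
  of pseudo-counted means; two-sided rank-sum p; BH within state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_preprocess import GeneExpressionMatrix

__all__ = [
    "DirectionalSignature",
    "build_consensus_signature",
    "build_response_signature",
    "build_disease_signatures",
    "rank_sum_de",
    "read_signature_tsv",
    "write_signature_tsv",
    "read_de_table",
    "read_gmt",
    "write_gmt",
]


@dataclass
class DirectionalSignature:
    """A named gene -> signed-score mapping with no zero scores.

    ``scores`` is a pandas Series indexed by unique gene symbols; positive
    values are up-genes, negative values down-genes.
    """

    name: str
    scores: pd.Series

    def __post_init__(self):
        s = pd.Series(self.scores, dtype=float)
        s.index = s.index.astype(str)
        if s.index.duplicated().any():
            raise ValueError(f"signature {self.name!r} lists a gene twice")
        if (~np.isfinite(s.to_numpy())).any() or (s == 0).any():
            raise ValueError(f"signature {self.name!r} scores must be finite and nonzero")
        s.index.name = None
        self.scores = s

    @property
    def genes(self) -> list:
        return self.scores.index.tolist()

    @property
    def n_up(self) -> int:
        return int((self.scores > 0).sum())

    @property
    def n_down(self) -> int:
        return int((self.scores < 0).sum())

    def negated(self, name: str | None = None) -> "DirectionalSignature":
        return DirectionalSignature(name or f"{self.name}_neg", -self.scores)

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def build_consensus_signature(
    profiles: Mapping[str, Mapping[str, float]],
    min_sign_frac: float = 0.75,
    min_median_abs: float = 1.0,
    name: str = "consensus",
) -> DirectionalSignature:
    """Consensus signature across >= 2 measurement contexts.

    A gene is retained iff the majority sign agrees across at least
    ``min_sign_frac`` of the contexts where it is measured, and the median of
    its absolute scores is at least ``min_median_abs``.  The retained score is
    the median of the signed scores.  Scores of exactly 0 carry no direction
    and are treated as unmeasured.
    """
    if len(profiles) < 2:
        raise ValueError("consensus requires at least 2 contexts")
    wide = pd.DataFrame({ctx: pd.Series(p, dtype=float) for ctx, p in profiles.items()})
    wide = wide.replace(0.0, np.nan)
    kept: dict[str, float] = {}
    for gene, row in wide.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size == 0:
            continue
        n_pos = int((vals > 0).sum())
        frac = max(n_pos, vals.size - n_pos) / vals.size
        med = float(np.median(vals))
        if frac >= min_sign_frac and float(np.median(np.abs(vals))) >= min_median_abs and med != 0:
            kept[str(gene)] = med
    return DirectionalSignature(name, pd.Series(kept, dtype=float))


def build_response_signature(
    de: pd.DataFrame,
    sd_mult: float = 2.0,
    alpha: float = 0.05,
    mode: str = "symmetric",
    name: str = "response",
) -> DirectionalSignature:
    """Response signature from a bulk DE table (columns gene, logFC, adj_p).

    The magnitude cutoff is ``t = mean(logFC) + sd_mult * sd(logFC)`` over all
    genes.  ``mode="symmetric"`` (default) keeps ``|logFC| > t``;
    ``mode="two_sided"`` keeps ``logFC > mean + sd_mult*sd`` or
    ``logFC < mean - sd_mult*sd``.  Either way ``adj_p < alpha`` is required
    and scores are the logFC values.
    """
    if de.empty:
        raise ValueError("DE table is empty")
    for col in ("gene", "logFC", "adj_p"):
        if col not in de.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    lfc = de["logFC"].to_numpy(dtype=float)
    mean = float(lfc.mean())
    sd = float(lfc.std(ddof=1)) if lfc.size > 1 else 0.0
    if mode == "symmetric":
        t = mean + sd_mult * sd
        pass_mag = np.abs(lfc) > t
    elif mode == "two_sided":
        pass_mag = (lfc > mean + sd_mult * sd) | (lfc < mean - sd_mult * sd)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = pass_mag & (de["adj_p"].to_numpy(dtype=float) < alpha) & (lfc != 0)
    if not keep.any():
        warnings.warn(f"response signature {name!r} retained zero genes", stacklevel=2)
    sub = de.loc[keep]
    return DirectionalSignature(name, pd.Series(sub["logFC"].to_numpy(), index=sub["gene"]))


def rank_sum_de(A: np.ndarray, B: np.ndarray, genes: list) -> pd.DataFrame:
    """Vectorized per-gene comparison of two lognorm cell groups.

    logFC is the log2 ratio of pseudo-counted de-logged means,
    ``log2((mean(expm1 A) + 1) / (mean(expm1 B) + 1))``; p-values come from a
    two-sided Wilcoxon rank-sum test (tie-corrected normal approximation) and
    are BH-adjusted across genes.  Rows with no variation get p = 1.
    """
    la = np.log2(np.expm1(A).mean(axis=1) + 1.0)
    lb = np.log2(np.expm1(B).mean(axis=1) + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = mannwhitneyu(A, B, axis=1, alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "logFC": la - lb, "p": p, "adj_p": adj})


def build_disease_signatures(
    expr: GeneExpressionMatrix,
    meta: pd.DataFrame,
    state_column: str,
    normal_states: set,
    subject_column: str | None = None,
    min_cells: int = 3,
):
    """Per-state pseudo-bulk disease signatures against pooled normal cells.

    ``meta`` must carry one row per cell (``cell_id``) with ``state_column``;
    states listed in ``normal_states`` form the pooled reference.  States with
    fewer than ``min_cells`` cells are skipped with a warning.  Returns a dict
    ``state -> DataFrame(gene, logFC, p, adj_p)``; with ``subject_column`` a
    dict ``subject -> {state: table}`` comparing each subject's tumor cells to
    the full normal reference.
    """
    if expr.layer != "lognorm":
        raise ValueError("build_disease_signatures expects the lognorm layer")
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    missing = [c for c in expr.cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"metadata lacks {len(missing)} cells, e.g. {missing[:3]}")
    states = meta.loc[expr.cell_ids, state_column]
    col_of = {c: i for i, c in enumerate(expr.cell_ids)}
    X = expr.dense()

    normal_idx = [col_of[c] for c in states.index[states.isin(normal_states)]]
    if len(normal_idx) < min_cells:
        raise ValueError("pooled normal reference has fewer than min_cells cells")
    B = X[:, normal_idx]

    def _per_group(group_meta: pd.DataFrame) -> dict:
        out: dict[str, pd.DataFrame] = {}
        for state, rows in group_meta.groupby(state_column, sort=True):
            if state in normal_states:
                continue
            idx = [col_of[c] for c in rows.index]
            if len(idx) < min_cells:
                warnings.warn(
                    f"state {state!r} has {len(idx)} < {min_cells} cells; skipped",
                    stacklevel=3,
                )
                continue
            out[str(state)] = rank_sum_de(X[:, idx], B, expr.gene_ids)
        return out

    tumor_meta = meta.loc[[c for c in expr.cell_ids if c in meta.index]]
    if subject_column is None:
        return _per_group(tumor_meta)
    return {
        str(subj): _per_group(rows)
        for subj, rows in tumor_meta.groupby(subject_column, sort=True)
    }


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def read_signature_tsv(path: str, name: str | None = None) -> DirectionalSignature:
    """Read a two-column (gene, score) TSV."""
    tbl = pd.read_csv(path, sep="\t")
    if not {"gene", "score"}.issubset(tbl.columns):
        raise ValueError(f"{path} must have columns gene and score")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(path))[0]
    return DirectionalSignature(name, pd.Series(tbl["score"].to_numpy(), index=tbl["gene"]))


def write_signature_tsv(sig: DirectionalSignature, path: str) -> None:
    pd.DataFrame({"gene": sig.genes, "score": sig.scores.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_de_table(path: str) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t")
    if not {"gene", "logFC", "adj_p"}.issubset(tbl.columns):
        raise ValueError(f"{path} must have columns gene, logFC, adj_p")
    return tbl


def read_gmt(path: str) -> dict:
    """Read a GMT gene-set file: name <TAB> description <TAB> gene...."""
    sets: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set name {parts[0]!r} in {path}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list], path: str) -> None:
    with open(path, "w") as fh:
        for nm, genes in sets.items():
            fh.write("\t".join([nm, nm] + list(genes)) + "\n")
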