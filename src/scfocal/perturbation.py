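"""In-silico perturbation: sensitive/resistant cell splits and their characterization.

Given one signature's per-cell connectivity, cells are split at a
"pseudo-dose" threshold tau: cells with rho > tau are predicted *resistant*
(their expression is concordant with the post-treatment response), cells with
rho <= tau predicted *sensitive*.  The split is characterized by per-subject
state-proportion shifts (paired signed-rank across subjects, BH across
states), by differential expression between populations, and by rank-sum
comparisons of connectivity across annotated groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon
from statsmodels.stats.multitest import multipletests

from .io_preprocess import GeneExpressionMatrix
from .signatures import rank_sum_de

__all__ = [
    "PerturbationSplit",
    "ProportionShiftTable",
    "split_cells",
    "proportion_shift",
    "de_between_populations",
    "compare_group_connectivity",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass
class PerturbationSplit:
    """Per-cell sensitive/resistant labels for one signature at threshold tau."""

    signature_id: str
    tau: float
    mode: str
    labels: pd.Series  # scored cells only; values in {sensitive, resistant}
    rho: pd.Series

    def cells(self, label: str) -> list:
        return self.labels.index[self.labels == label].tolist()


@dataclass
class ProportionShiftTable:
    """Per-subject state-proportion differences (resistant - sensitive) and tests."""

    deltas: pd.DataFrame  # subjects x states
    stats: pd.DataFrame  # per state: p, adj_p


def split_cells(
    conn_row: pd.Series,
    mode: str = "fixed",
    tau: float = 0.0,
    signature_id: str | None = None,
) -> PerturbationSplit:
    """Label cells resistant (rho > tau) or sensitive (rho <= tau).

    ``mode="fixed"`` uses the given tau (default 0, the sign split);
    ``mode="mean"`` sets tau to the mean of the non-missing connectivities.
    Cells with missing rho are left unlabeled and excluded downstream.
    """
    rho = pd.Series(conn_row, dtype=float).dropna()
    if rho.empty:
        raise ValueError("no non-missing connectivity values to split on")
    if mode == "mean":
        tau = float(rho.mean())
    elif mode != "fixed":
        raise ValueError(f"unknown threshold mode {mode!r}")
    labels = pd.Series(np.where(rho > tau, RESISTANT, SENSITIVE), index=rho.index)
    return PerturbationSplit(
        signature_id=signature_id or str(getattr(conn_row, "name", "signature")),
        tau=float(tau),
        mode=mode,
        labels=labels,
        rho=rho,
    )


def proportion_shift(
    split: PerturbationSplit,
    meta: pd.DataFrame,
    state_column: str,
    subject_column: str,
) -> ProportionShiftTable:
    """Per-subject, per-state proportion difference between the two populations.

    For each subject with cells in both populations, state proportions are
    computed within the resistant and sensitive populations separately and
    differenced (resistant - sensitive; each per-subject delta vector sums to
    0).  Per state, a two-sided paired signed-rank test across subjects
    (exact null for small subject counts) is BH-adjusted across states.
    """
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    cells = [c for c in split.labels.index if c in meta.index]
    tbl = pd.DataFrame(
        {
            "label": split.labels.loc[cells],
            "state": meta.loc[cells, state_column],
            "subject": meta.loc[cells, subject_column],
        }
    )
    states = sorted(tbl["state"].unique())
    rows = {}
    for subj, grp in tbl.groupby("subject", sort=True):
        by = grp.groupby("label")["state"].value_counts()
        if RESISTANT not in grp["label"].values or SENSITIVE not in grp["label"].values:
            warnings.warn(f"subject {subj!r} lacks one population; dropped", stacklevel=2)
            continue
        res = by[RESISTANT].reindex(states, fill_value=0)
        sen = by[SENSITIVE].reindex(states, fill_value=0)
        rows[subj] = res / res.sum() - sen / sen.sum()
    if len(rows) < 3:
        raise ValueError("proportion_shift needs >= 3 subjects with both populations")
    deltas = pd.DataFrame(rows).T
    deltas.index.name = "subject"
    pvals = []
    for state in states:
        d = deltas[state].to_numpy()
        if np.allclose(d, 0):
            pvals.append(1.0)
            continue
        pvals.append(float(wilcoxon(d, alternative="two-sided", method="auto").pvalue))
    adj = multipletests(pvals, method="fdr_bh")[1]
    stats = pd.DataFrame({"state": states, "p": pvals, "adj_p": adj}).set_index("state")
    return ProportionShiftTable(deltas=deltas, stats=stats)


def de_between_populations(
    expr: GeneExpressionMatrix,
    split: PerturbationSplit,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Rank-sum differential expression, resistant versus sensitive cells.

    logFC is log2 of the pseudo-counted de-logged mean ratio (resistant over
    sensitive); every input gene appears in the output.
    """
    if expr.layer != "lognorm":
        raise ValueError("de_between_populations expects the lognorm layer")
    col_of = {c: i for i, c in enumerate(expr.cell_ids)}
    res = [col_of[c] for c in split.cells(RESISTANT) if c in col_of]
    sen = [col_of[c] for c in split.cells(SENSITIVE) if c in col_of]
    if len(res) < min_cells or len(sen) < min_cells:
        raise ValueError(
            f"populations too small ({len(res)} resistant, {len(sen)} sensitive; "
            f"need >= {min_cells} each)"
        )
    X = expr.dense()
    return rank_sum_de(X[:, res], X[:, sen], expr.gene_ids)


def compare_group_connectivity(
    conn_row: pd.Series,
    meta: pd.DataFrame,
    group_column: str,
):
    """Two-sided Wilcoxon rank-sum test of connectivity between two groups.

    Uses the continuity-corrected normal approximation.  Returns the
    mannwhitneyu result (statistic is the U of the first group in sorted
    group order).
    """
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    rho = pd.Series(conn_row, dtype=float).dropna()
    cells = [c for c in rho.index if c in meta.index]
    groups = meta.loc[cells, group_column]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(names)}: {names}")
    a = rho.loc[[c for c in cells if groups[c] == names[0]]].to_numpy()
    b = rho.loc[[c for c in cells if groups[c] == names[1]]].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 cells")
    return mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
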