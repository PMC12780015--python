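"""Disease-signature reversal scoring and the combination index for partner drugs.

Two quantities feed the index for a candidate drug against a reference
perturbation:

* ``log2FC`` — the candidate's differential connectivity between the
  reference-resistant and reference-sensitive populations (negative =
  connectivity drops in resistant cells), aggregated across subjects;
* ``rcc`` — the candidate's mean connectivity over the resistant population
  (negative = the candidate's response signature disagrees with resistant
  cells' expression).

The combination index is their product, defined only when BOTH are strictly
negative:

    ci = log2FC * rcc * I(log2FC < 0 and rcc < 0)

so a present ci is always positive, and larger values flag candidates that
selectively disagree with the cells the reference drug is predicted to
spare.  Present ci values are min-max scaled to [0, 1] for ranking.

The module also scores signature reversal of disease signatures via the
discordance ratio: among significant shared genes, the count moving opposite
the disease signature over the count moving with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import score_connectivity
from .differential import aggregate_subject_logfc, fit_moderated, transform
from .io_preprocess import GeneExpressionMatrix
from .perturbation import RESISTANT, PerturbationSplit, split_cells
from .signatures import DirectionalSignature

__all__ = [
    "discordance_ratio",
    "mean_resistant_connectivity",
    "combination_index",
    "score_reference_combinations",
]


def discordance_ratio(
    sig: DirectionalSignature,
    disease: pd.DataFrame,
    disease_alpha: float = 0.05,
) -> tuple:
    """Ratio of discordant to concordant genes between a signature and a disease state.

    The disease table (columns gene, logFC, adj_p) is filtered to
    ``adj_p < disease_alpha`` first.  Over shared genes, *discordant* genes
    have opposite signs of (signature score, disease logFC) and *concordant*
    genes the same sign; genes with a zero on either side carry no direction
    and count for neither.  Returns ``(ratio, n_discordant, n_concordant)``
    where ratio is ``inf`` when concordant = 0 < discordant and NaN when both
    counts are 0.
    """
    sub = disease.loc[disease["adj_p"].to_numpy(dtype=float) < disease_alpha]
    shared = sub.loc[sub["gene"].isin(sig.scores.index)]
    if shared.empty:
        raise ValueError(
            f"signature {sig.name!r} shares no significant genes with the disease table"
        )
    s_sig = np.sign(sig.scores.loc[shared["gene"]].to_numpy())
    s_dis = np.sign(shared["logFC"].to_numpy(dtype=float))
    prod = s_sig * s_dis
    n_disc = int((prod < 0).sum())
    n_conc = int((prod > 0).sum())
    if n_conc > 0:
        ratio = n_disc / n_conc
    elif n_disc > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")
    return ratio, n_disc, n_conc


def mean_resistant_connectivity(conn: pd.DataFrame, split: PerturbationSplit) -> pd.Series:
    """Per-signature mean connectivity over resistant-labeled cells (NaN skipped)."""
    res = [c for c in split.cells(RESISTANT) if c in conn.columns]
    if not res:
        raise ValueError("no resistant cells available")
    return conn.loc[:, res].mean(axis=1)


def combination_index(diff: pd.DataFrame, rcc: pd.Series) -> pd.DataFrame:
    """Combination table from a differential table and mean resistant connectivities.

    ``diff`` must carry a ``log2FC`` column indexed by signature; ``rcc`` is a
    per-signature Series.  The index is computed on the shared signatures.
    ``ci_scaled`` min-max scales the present ci values to [0, 1] (a single
    present value scales to 1.0); ``rank`` orders present ci descending.
    """
    shared = diff.index.intersection(rcc.index)
    if shared.empty:
        raise ValueError("diff table and rcc share no signatures")
    logfc = diff.loc[shared, "log2FC"].astype(float)
    r = rcc.loc[shared].astype(float)
    eligible = (logfc < 0) & (r < 0)
    ci = pd.Series(np.where(eligible, logfc * r, np.nan), index=shared)
    present = ci.dropna()
    scaled = pd.Series(np.nan, index=shared)
    if len(present) == 1:
        scaled.loc[present.index] = 1.0
    elif len(present) > 1:
        lo, hi = present.min(), present.max()
        scaled.loc[present.index] = 1.0 if hi == lo else (present - lo) / (hi - lo)
    rank = ci.rank(ascending=False, method="min")
    out = pd.DataFrame(
        {"log2fc": logfc, "rcc": r, "ci": ci, "ci_scaled": scaled, "rank": rank}
    )
    out.index.name = "signature"
    return out


@dataclass
class ReferenceCombinationResult:
    """Output of the end-to-end reference-combination pipeline."""

    table: pd.DataFrame
    split: PerturbationSplit
    connectivity: pd.DataFrame
    per_subject: dict


def score_reference_combinations(
    expr: GeneExpressionMatrix,
    candidates: list,
    reference: DirectionalSignature,
    meta: pd.DataFrame,
    subject_column: str,
    min_overlap: int = 10,
    transform_mode: str = "fisher_z",
    min_cells_per_population: int = 2,
) -> ReferenceCombinationResult:
    """Rank candidate signatures for combination with a reference perturbation.

    Pipeline: connectivity scoring of reference + candidates on the scaled
    matrix; mean-threshold split on the reference; per-subject moderated
    differential connectivity of the candidates across the split; mean
    log2FC across subjects; mean resistant-cell connectivity over the pooled
    resistant population; combination index with min-max scaling.  Subjects
    lacking ``min_cells_per_population`` cells in either population are
    skipped with a warning.
    """
    names = [reference.name] + [c.name for c in candidates]
    if len(set(names)) != len(names):
        raise ValueError("reference and candidate names must be unique")
    try:
        conn = score_connectivity(expr, [reference] + list(candidates), min_overlap=min_overlap)
    except ValueError as exc:
        raise ValueError(f"connectivity stage failed: {exc}") from exc
    split = split_cells(conn.loc[reference.name], mode="mean", signature_id=reference.name)
    cand_conn = conn.drop(index=reference.name)
    tc = transform(cand_conn, mode=transform_mode)
    meta_idx = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    per_subject: dict[str, pd.DataFrame] = {}
    for subj, rows in meta_idx.loc[[c for c in split.labels.index if c in meta_idx.index]].groupby(
        subject_column, sort=True
    ):
        cells = [c for c in rows.index if c in tc.values.columns]
        labels = split.labels.loc[cells]
        counts = labels.value_counts()
        if (
            counts.get(RESISTANT, 0) < min_cells_per_population
            or counts.get("sensitive", 0) < min_cells_per_population
        ):
            warnings.warn(f"subject {subj!r} lacks both populations; skipped", stacklevel=2)
            continue
        sub_split = PerturbationSplit(
            signature_id=split.signature_id,
            tau=split.tau,
            mode=split.mode,
            labels=labels,
            rho=split.rho.loc[cells],
        )
        sub_tc = type(tc)(values=tc.values.loc[:, cells], mode=tc.mode)
        try:
            tbl, _ = fit_moderated(sub_tc, sub_split)
        except ValueError as exc:
            warnings.warn(f"model stage skipped subject {subj!r}: {exc}", stacklevel=2)
            continue
        per_subject[str(subj)] = tbl
    if not per_subject:
        raise ValueError("model stage: no subject had both populations")
    agg = aggregate_subject_logfc(per_subject)
    rcc = mean_resistant_connectivity(cand_conn, split)
    table = combination_index(agg, rcc)
    return ReferenceCombinationResult(
        table=table, split=split, connectivity=conn, per_subject=per_subject
    )
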