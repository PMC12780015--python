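"""Moderated differential-connectivity models across a sensitive/resistant split.

Connectivity values (Spearman rho per signature per cell) are variance-
stabilized — Fisher's Z (``atanh``) or a pseudo-counted log2 — and fit, one
linear model per signature, against a design of intercept + population
indicator + optional subject covariates.  Residual variances are shrunk
toward a common prior by the standard empirical-Bayes formula

    s2_post = (d0 * s0^2 + df * s^2) / (d0 + df),

with the prior degrees of freedom ``d0`` and prior variance ``s0^2``
estimated by moment-matching the log residual variances to a scaled-F
distribution (digamma/trigamma moments; trigamma inverse by Newton
iteration).  Moderated t-statistics use ``d0 + df`` degrees of freedom and
are BH-adjusted across signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .perturbation import RESISTANT, SENSITIVE, PerturbationSplit

__all__ = [
    "TransformedConnectivity",
    "EBayesParams",
    "transform",
    "fit_moderated",
    "aggregate_subject_logfc",
    "compare_logfc_sets",
    "trigamma_inverse",
]

_FISHER_CLIP = 1.0 - 1e-7
_PSEUDO_EPS = 1e-6


@dataclass
class TransformedConnectivity:
    """Signatures x cells connectivity values after a variance transform."""

    values: pd.DataFrame
    mode: str


@dataclass
class EBayesParams:
    """Prior degrees of freedom and prior residual variance of the shrinkage model."""

    d0: float
    s0_sq: float


def transform(conn: pd.DataFrame, mode: str = "fisher_z") -> TransformedConnectivity:
    """Variance-stabilize a connectivity matrix.

    ``fisher_z``: atanh(rho) with rho clipped to +-(1 - 1e-7) so boundary
    correlations stay finite.  ``pseudocount_log``: log2(rho + 1 + 1e-6),
    defined down to rho = -1.  ``none``: identity.
    """
    if mode == "fisher_z":
        vals = np.arctanh(conn.clip(-_FISHER_CLIP, _FISHER_CLIP))
    elif mode == "pseudocount_log":
        vals = np.log2(conn + 1.0 + _PSEUDO_EPS)
    elif mode == "none":
        vals = conn.copy()
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return TransformedConnectivity(values=pd.DataFrame(vals), mode=mode)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on the canonical scheme)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, df: int) -> EBayesParams:
    """Moment-match log residual variances to a scaled-F model."""
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
    return EBayesParams(d0=d0, s0_sq=s0)


def _build_design(
    labels: pd.Series,
    meta: pd.DataFrame | None,
    covariate_columns,
) -> tuple:
    cols = {"intercept": np.ones(len(labels)), "population": (labels == RESISTANT).astype(float)}
    if covariate_columns:
        if meta is None:
            raise ValueError("covariate columns requested but no metadata given")
        meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
        for col in covariate_columns:
            dummies = pd.get_dummies(
                meta.loc[labels.index, col].astype(str), prefix=col, drop_first=True
            )
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def fit_moderated(
    tc: TransformedConnectivity,
    split: PerturbationSplit,
    meta: pd.DataFrame | None = None,
    covariate_columns=(),
    prior_df: float | None = None,
) -> tuple:
    """Per-signature moderated linear model of transformed connectivity.

    Fits OLS of the transformed values on intercept + resistant indicator
    (+ covariate dummies), shrinks residual variances toward the estimated
    prior, and reports the population coefficient (``log2FC``, resistant
    minus sensitive on the transformed scale), moderated t, two-sided p with
    ``d0 + df`` degrees of freedom, BH-adjusted p, raw group means, and the
    posterior variances.  ``prior_df`` overrides the estimated d0 (0 recovers
    ordinary least-squares t-statistics; very large values shrink every
    variance to the prior s0^2).

    Returns ``(table, EBayesParams)``.
    """
    labeled = [c for c in tc.values.columns if c in split.labels.index]
    labels = split.labels.loc[labeled]
    Y = tc.values.loc[:, labeled]
    ok = ~Y.isna().any(axis=1)
    if (~ok).any():
        warnings.warn(
            f"dropping {int((~ok).sum())} signatures with missing transformed values",
            stacklevel=2,
        )
    Y = Y.loc[ok]
    if Y.empty:
        raise ValueError("no signatures with complete transformed values")
    X, _names = _build_design(labels, meta, list(covariate_columns))
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError(f"residual degrees of freedom {df} < 1")
    Ym = Y.to_numpy()  # signatures x cells
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Ym.T)  # p x signatures
    resid = Ym.T - X @ coef
    s2 = (resid**2).sum(axis=0) / df
    Rinv = np.linalg.inv(R)
    unscaled = (Rinv**2).sum(axis=1)  # diag of (X'X)^-1
    params = _estimate_prior(s2, df)
    d0 = params.d0 if prior_df is None else float(prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, params.s0_sq)
        df_total = 1e12
    else:
        s2_post = (d0 * params.s0_sq + df * s2) / (d0 + df) if d0 > 0 else s2
        df_total = d0 + df
    j = 1  # population coefficient
    beta = coef[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / np.sqrt(s2_post * unscaled[j])
    pvals = 2.0 * t_dist.sf(np.abs(tstat), df=min(df_total, 1e12))
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    adj = multipletests(pvals, method="fdr_bh")[1]
    res_cells = labels.index[labels == RESISTANT]
    sen_cells = labels.index[labels == SENSITIVE]
    table = pd.DataFrame(
        {
            "log2FC": beta,
            "t": tstat,
            "p": pvals,
            "adj_p": adj,
            "mean_sensitive": Y.loc[:, sen_cells].mean(axis=1) if len(sen_cells) else np.nan,
            "mean_resistant": Y.loc[:, res_cells].mean(axis=1) if len(res_cells) else np.nan,
            "s2_post": s2_post,
        },
        index=Y.index,
    )
    table.index.name = "signature"
    return table, EBayesParams(d0=d0, s0_sq=params.s0_sq)


def aggregate_subject_logfc(per_subject: dict) -> pd.DataFrame:
    """Average per-subject differential-connectivity log2FC by signature.

    ``per_subject`` maps subject id to a fit_moderated table.  Returns a
    DataFrame with the arithmetic mean ``log2FC`` over subjects where the
    signature was estimable and the contributing-subject count.
    """
    if not per_subject:
        raise ValueError("no subject tables to aggregate")
    wide = pd.DataFrame({subj: tbl["log2FC"] for subj, tbl in per_subject.items()})
    n = wide.notna().sum(axis=1)
    empty = n == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} signatures absent from every subject; dropped",
            stacklevel=2,
        )
    out = pd.DataFrame({"log2FC": wide.mean(axis=1), "n_subjects": n}).loc[~empty]
    out.index.name = "signature"
    return out


def compare_logfc_sets(
    predicted: pd.Series,
    observed: pd.Series,
    class_map: dict | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Spearman agreement of predicted versus observed log2FC, per class.

    p-values use the two-sided t approximation with n - 2 degrees of freedom.
    Classes with fewer than ``min_shared`` shared signatures are skipped; the
    overall row ``"all"`` covers every shared signature.
    """
    shared = predicted.index.intersection(observed.index)
    if len(shared) < min_shared:
        raise ValueError(f"fewer than {min_shared} shared signatures overall")
    groups: dict[str, list] = {"all": list(shared)}
    if class_map:
        for sig in shared:
            cls = class_map.get(sig)
            if cls is not None:
                groups.setdefault(str(cls), []).append(sig)
    rows = []
    for cls, sigs in groups.items():
        if len(sigs) < min_shared:
            continue
        a = rankdata(predicted.loc[sigs].to_numpy())
        b = rankdata(observed.loc[sigs].to_numpy())
        rho = float(np.corrcoef(a, b)[0, 1])
        n = len(sigs)
        if abs(rho) >= 1.0:
            pval = 0.0
        else:
            tval = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            pval = float(2.0 * t_dist.sf(abs(tval), df=n - 2))
        rows.append((cls, rho, pval, n))
    return pd.DataFrame(rows, columns=["class", "rho", "p", "n"]).set_index("class")
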