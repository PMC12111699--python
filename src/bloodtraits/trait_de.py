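"""Continuous-trait differential expression by double residualization.

Both the trait and every gene's log-normalized expression are adjusted for
the same confounders — breed and pen (fixed), sire (random), age and blood
cell composition (NEU, LYM, MONO, EOS, BAS fractions of WBC plus the RBC
count) — using the REML mixed-model engine.  Conditional residuals are
extracted, genes are correlated with the adjusted trait one at a time
(Pearson r with a two-sided t test), and p-values are Benjamini–Hochberg
adjusted against the total number of genes tested.  Genes with FDR-adjusted
p < 0.1 are flagged.

Degrees of freedom for the correlation test: residual vectors live in the
(n − rank(X))-dimensional complement of the fixed-effect design, so the null
distribution of their correlation is that of n − rank(X) exchangeable
observations, not n.  The default ``df_method="effective"`` therefore uses
n − rank(X) − 1 df, which keeps the false-discovery rate at its nominal
level; ``df_method="simple"`` uses the textbook n − 2 and reproduces the
common practice of correlating residuals as if they were raw data (it is
anticonservative in exactly the way the effective-df analysis predicts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import build_design, fit_reml, fit_reml_batch

__all__ = [
    "AdjustedData",
    "cell_proportion_covariates",
    "adjust",
    "correlate",
    "correlation_pvalue",
    "bh_adjust",
    "run_de",
]

FDR_THRESHOLD = 0.1
LEUKOCYTE_TYPES = ["NEU", "LYM", "MONO", "EOS", "BAS"]


@dataclass
class AdjustedData:
    """Confounder-adjusted expression matrix and trait vector."""

    resid_expr: pd.DataFrame      # gene × sample conditional residuals
    resid_trait: pd.Series        # per-sample residual of the trait
    covariate_set: list[str]
    rank_x: int = 0               # columns absorbed by the fixed design


def correlation_pvalue(r: float | np.ndarray, df: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation at ``df`` degrees of freedom.

    p = 2·P(T_df > |r|·sqrt(df / (1 − r²))).
    """
    r = np.clip(np.asarray(r, float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return np.clip(2.0 * stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny, 1.0)


def cell_proportion_covariates(cbc: pd.DataFrame) -> pd.DataFrame:
    """Blood-cell composition covariates for the adjustment models.

    The five leukocyte differential counts are converted to fractions of
    WBC; RBC enters as its absolute count (10¹²/L), since a red-cell count
    has no meaningful proportion of the leukocyte total.
    """
    wbc = cbc["WBC"].to_numpy(float)
    if np.any(wbc <= 0):
        raise ValueError("WBC must be positive for cell proportions")
    out = pd.DataFrame(index=cbc.index)
    for p in LEUKOCYTE_TYPES:
        out[f"{p}_frac"] = cbc[p].to_numpy(float) / wbc
    out["RBC"] = cbc["RBC"].to_numpy(float)
    return out


def adjust(
    expr_lognorm: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    meta: pd.DataFrame,
    cellprops: pd.DataFrame,
) -> AdjustedData:
    """Residualize expression and trait on the shared confounder design.

    One design (breed + pen fixed, age + six cell-composition covariates,
    sire random) is built once; the trait and every gene are fitted by REML
    independently against it and their conditional residuals
    (y − Xβ − Zu) retained.
    """
    y = np.asarray(trait, float)
    if len(y) != len(meta) or expr_lognorm.shape[1] != len(meta):
        raise ValueError("trait, metadata and expression must share samples")
    d = build_design(meta, covariates=cellprops.reset_index(drop=True))
    trait_fit = fit_reml(y, d)
    batch = fit_reml_batch(expr_lognorm.to_numpy(float).T, d)
    resid_expr = pd.DataFrame(
        batch["resid_conditional"].T,
        index=expr_lognorm.index,
        columns=expr_lognorm.columns,
    )
    return AdjustedData(
        resid_expr=resid_expr,
        resid_trait=pd.Series(trait_fit.resid_conditional, index=expr_lognorm.columns),
        covariate_set=list(d.x_names) + list(d.z_names),
        rank_x=d.rank,
    )


def correlate(adj: AdjustedData, df_method: str = "effective") -> pd.DataFrame:
    """Gene-wise Pearson correlation with the adjusted trait.

    p-values are two-sided from t = r·sqrt(df/(1−r²)) with df = n − rank(X)
    − 1 under the default ``df_method="effective"`` (see module docstring),
    or df = n − 2 under ``df_method="simple"``.  Genes whose residuals have
    zero variance get r = 0, p = 1 and a degenerate flag.
    """
    E = adj.resid_expr.to_numpy(float)
    t_vec = adj.resid_trait.to_numpy(float)
    n = len(t_vec)
    if n < 4:
        raise ValueError("need at least 4 retained samples")
    if df_method == "effective":
        df = n - adj.rank_x - 1
    elif df_method == "simple":
        df = n - 2
    else:
        raise ValueError("df_method must be 'effective' or 'simple'")
    if df < 1:
        raise ValueError("not enough retained samples for the design size")
    Ec = E - E.mean(axis=1, keepdims=True)
    tc = t_vec - t_vec.mean()
    denom_e = np.sqrt(np.einsum("ij,ij->i", Ec, Ec))
    denom_t = np.sqrt(tc @ tc)
    # numerically-zero residual vectors (constant genes fitted exactly)
    tol = 1e-10 * np.sqrt(n)
    degenerate = (denom_e <= tol) | (denom_t <= tol)
    denom = np.where(degenerate, 1.0, denom_e * denom_t)
    r = np.clip((Ec @ tc) / denom, -1.0, 1.0)
    r[degenerate] = 0.0
    p = correlation_pvalue(r, df)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "gene_id": adj.resid_expr.index,
            "reg": r,
            "p_nominal": p,
            "degenerate": degenerate,
        }
    )


def bh_adjust(p: np.ndarray, m_total: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``m_total`` lets a subset of p-values be adjusted against the full test
    count (e.g. a printed shortlist against all genes tested); it must be at
    least ``len(p)``.  adj_(i) = min(1, min_{j≥i} m_total·p_(j)/j) in sorted
    order, mapped back to the input order.
    """
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError("m_total must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def run_de(
    lognorm: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    meta: pd.DataFrame,
    cbc: pd.DataFrame,
    fdr: float = FDR_THRESHOLD,
    m_total: int | None = None,
    df_method: str = "effective",
) -> pd.DataFrame:
    """Full DE pipeline: adjust → correlate → BH adjust → flag.

    ``lognorm`` must already be restricted to retained samples and filtered
    genes (the preprocessing stage's output).  ``m_total`` defaults to the
    number of genes tested.  Output is sorted by adjusted then nominal p.
    """
    cellprops = cell_proportion_covariates(cbc)
    adj = adjust(lognorm, trait, meta, cellprops)
    res = correlate(adj, df_method=df_method)
    res["p_fdr"] = bh_adjust(res["p_nominal"].to_numpy(), m_total)
    res["significant"] = res["p_fdr"] < fdr
    res = res.sort_values(
        ["p_fdr", "p_nominal", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    return res[["gene_id", "reg", "p_nominal", "p_fdr", "significant", "degenerate"]]
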