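"""Count-matrix preprocessing for the blood transcriptome pipeline.

Low-expression filtering, median-of-ratios size factors, log2 normalisation,
variance filtering + PCA, and confidence-ellipse outlier flagging of samples
in the (PC1, PC2) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrepResult",
    "filter_low_expression",
    "size_factors",
    "log_normalize",
    "pca_with_variance_filter",
    "ellipse_outliers",
    "prep_pipeline",
]


class NormalizationError(ValueError):
    pass


class PCAError(ValueError):
    pass


@dataclass
class PrepResult:
    """Everything the preprocessing stage produced, sample QC included."""

    kept_gene_ids: list[str]
    size_factors: pd.Series
    lognorm: pd.DataFrame
    pc_scores: pd.DataFrame
    pc_varexp: np.ndarray
    outlier_ids: list[str]
    retained_ids: list[str]
    filter_log: dict[str, int] = field(default_factory=dict)


def _validate_counts(cm: pd.DataFrame) -> None:
    if cm.index.duplicated().any() or cm.columns.duplicated().any():
        raise ValueError("gene/sample identifiers must be unique")
    vals = cm.to_numpy()
    if (vals < 0).any():
        bad = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative count at gene '{cm.index[bad[0]]}', "
            f"sample '{cm.columns[bad[1]]}': {vals[bad[0], bad[1]]}"
        )


def filter_low_expression(
    cm: pd.DataFrame,
    mean_thresh: float = 10.0,
    zero_frac: float = 0.8,
    logic: str = "or",
) -> pd.Series:
    """Boolean keep-mask over genes.

    With ``logic="or"`` (default) a gene is removed if its mean count across
    samples is below ``mean_thresh`` OR it is zero in more than ``zero_frac``
    of samples; ``logic="and"`` requires both.  Removal counts per criterion
    are attached as ``mask.attrs['filter_log']``.
    """
    if cm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    _validate_counts(cm)
    vals = cm.to_numpy(float)
    low_mean = vals.mean(axis=1) < mean_thresh
    too_zero = (vals == 0).mean(axis=1) > zero_frac
    if logic == "or":
        remove = low_mean | too_zero
    elif logic == "and":
        remove = low_mean & too_zero
    else:
        raise ValueError("logic must be 'or' or 'and'")
    mask = pd.Series(~remove, index=cm.index, name="keep")
    mask.attrs["filter_log"] = {
        "n_genes": int(len(mask)),
        "low_mean": int(low_mean.sum()),
        "high_zero_fraction": int(too_zero.sum()),
        "removed": int(remove.sum()),
        "kept": int((~remove).sum()),
    }
    return mask


def size_factors(cm: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean across samples over genes
    with all-positive counts; each sample's factor is the median over those
    genes of count/reference.  Factors are not rescaled afterwards.
    """
    _validate_counts(cm)
    vals = cm.to_numpy(float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; "
            "filter low-expression genes first"
        )
    sub = vals[positive]
    ref = np.exp(np.log(sub).mean(axis=1))  # per-gene geometric mean
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=cm.columns, name="size_factor")


def log_normalize(cm: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), gene × sample."""
    f = factors.reindex(cm.columns).to_numpy(float)
    if not np.all(f > 0):
        raise NormalizationError("size factors must be positive")
    return pd.DataFrame(
        np.log2(cm.to_numpy(float) / f[None, :] + 1.0),
        index=cm.index,
        columns=cm.columns,
    )


def pca_with_variance_filter(
    lognorm: pd.DataFrame,
    drop_frac: float = 0.10,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples after dropping the lowest-variance genes.

    Genes are ranked by row variance and the lowest ``drop_frac`` removed;
    the remaining matrix is gene-centred and the samples projected onto the
    top right-singular vectors.  Sign convention: within each component the
    largest-magnitude sample score is made positive, so results do not
    depend on LAPACK sign choices.
    """
    vals = lognorm.to_numpy(float)
    if vals.shape[0] < 10:
        raise PCAError("need at least 10 genes for PCA")
    row_var = vals.var(axis=1)
    if np.allclose(row_var, 0):
        raise PCAError("constant matrix: no variance for PCA")
    n_drop = int(np.floor(drop_frac * len(row_var)))
    if n_drop > 0:
        order = np.argsort(row_var, kind="stable")
        keep = np.sort(order[n_drop:])
        vals = vals[keep]
    centered = vals - vals.mean(axis=1, keepdims=True)
    # samples are observations: SVD of genes × samples gives sample scores in V
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    n_components = min(n_components, len(s))
    scores = (Vt[:n_components] * s[:n_components, None]).T  # samples × k
    total = float(np.sum(s**2))
    if total == 0:
        raise PCAError("no variance after filtering")
    varexp = s[:n_components] ** 2 / total
    for j in range(scores.shape[1]):
        i_max = int(np.argmax(np.abs(scores[:, j])))
        if scores[i_max, j] < 0:
            scores[:, j] = -scores[:, j]
    pc = pd.DataFrame(
        scores,
        index=lognorm.columns,
        columns=[f"PC{j + 1}" for j in range(scores.shape[1])],
    )
    return pc, varexp


def ellipse_outliers(pc_scores: pd.DataFrame, level: float = 0.985) -> list[str]:
    """Samples outside the ``level`` confidence ellipse in the PC1/PC2 plane.

    The ellipse is the set of points whose squared Mahalanobis distance from
    the sample mean, under the sample covariance of (PC1, PC2), is at most
    the chi-square(2) quantile at ``level``.
    """
    if pc_scores.shape[0] < 10:
        raise ValueError("need at least 10 samples for outlier detection")
    if pc_scores.shape[1] < 2:
        raise ValueError("need 2 principal components")
    xy = pc_scores.iloc[:, :2].to_numpy(float)
    mu = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate (singular) PC score covariance")
    d2 = np.einsum("ij,jk,ik->i", xy - mu, np.linalg.inv(cov), xy - mu)
    cut = stats.chi2.ppf(level, df=2)
    return sorted(pc_scores.index[d2 > cut])


def prep_pipeline(
    cm: pd.DataFrame,
    mean_thresh: float = 10.0,
    zero_frac: float = 0.8,
    filter_logic: str = "or",
    drop_frac: float = 0.10,
    ellipse_level: float = 0.985,
) -> PrepResult:
    """Full preprocessing: filter → normalize → log → PCA → ellipse QC."""
    mask = filter_low_expression(cm, mean_thresh, zero_frac, filter_logic)
    kept = cm.loc[mask]
    sf = size_factors(kept)
    lognorm = log_normalize(kept, sf)
    pc, varexp = pca_with_variance_filter(lognorm, drop_frac=drop_frac)
    outliers = ellipse_outliers(pc, level=ellipse_level)
    retained = [s for s in cm.columns if s not in set(outliers)]
    return PrepResult(
        kept_gene_ids=list(kept.index),
        size_factors=sf,
        lognorm=lognorm,
        pc_scores=pc,
        pc_varexp=varexp,
        outlier_ids=list(outliers),
        retained_ids=retained,
        filter_log=dict(mask.attrs.get("filter_log", {})),
    )
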