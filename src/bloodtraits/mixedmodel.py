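"""Single-random-effect linear mixed model fitted by REML.

The model is

    y = X beta + Z u + e,    u ~ N(0, sigma2_s I_q),    e ~ N(0, sigma2_e I_n)

with ``X`` a fixed-effect design (intercept, dummy-coded factors, numeric
covariates) and ``Z`` a one-hot indicator of a single grouping factor (here:
sire).  The marginal covariance is ``V = sigma2_e (I + lambda Z Z')`` with
variance ratio ``lambda = sigma2_s / sigma2_e``; REML estimation profiles the
criterion over ``lambda`` on a log grid followed by golden-section refinement,
then recovers both components in closed form.  At the ``lambda = 0`` boundary
the fit reduces exactly to ordinary least squares.

All per-``lambda`` algebra runs in the thin-SVD basis of ``Z`` so a fit costs
O(n p) per criterion evaluation, and a batched variant (:func:`fit_reml_batch`)
shares the design across thousands of response vectors, which is what the
gene-wise confounder adjustment needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrices",
    "LMMFit",
    "build_design",
    "fit_reml",
    "fit_reml_batch",
    "reml_loglik_at",
    "wald_p",
    "model_r2",
    "marginal_r2",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0

# log10(lambda) grid endpoints for the profile search
_LOG_LAM_LO, _LOG_LAM_HI, _N_GRID = -6.0, 3.0, 61


class ModelSpecificationError(ValueError):
    """Raised when a design cannot be built (e.g. a single-level factor)."""


class AliasedCoefficientError(KeyError):
    """Raised when a requested coefficient was dropped as linearly dependent."""


@dataclass
class DesignMatrices:
    """Fixed- and random-effect design matrices with rank bookkeeping."""

    X: np.ndarray
    Z: np.ndarray
    x_names: list[str]
    z_names: list[str]
    rank: int
    dropped_columns: list[str] = field(default_factory=list)
    # thin SVD of Z, cached for REML: Z = Uz diag(sz) Vz'
    _Uz: np.ndarray | None = field(default=None, repr=False)
    _sz2: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def z_svd(self) -> tuple[np.ndarray, np.ndarray]:
        """Thin SVD factors of Z (left vectors and squared singular values)."""
        if self._Uz is None:
            Uz, sz, _ = np.linalg.svd(self.Z, full_matrices=False)
            keep = sz > sz[0] * 1e-12 if sz.size else np.zeros(0, bool)
            self._Uz, self._sz2 = Uz[:, keep], sz[keep] ** 2
        return self._Uz, self._sz2


@dataclass
class LMMFit:
    """REML fit: coefficients, BLUPs, variance components and residuals."""

    beta: np.ndarray
    se_beta: np.ndarray
    u: np.ndarray
    sigma2_sire: float
    sigma2_resid: float
    fitted_marginal: np.ndarray
    fitted_conditional: np.ndarray
    resid_conditional: np.ndarray
    reml_loglik: float
    converged: bool
    x_names: list[str]
    z_names: list[str]
    n: int
    rank_x: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.x_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.se_beta[self.x_names.index(name)])

    def summary(self) -> str:
        """Plain-text model summary for logging."""
        lines = [
            f"LMM fit: n={self.n}, rank(X)={self.rank_x}, "
            f"converged={self.converged}",
            f"  sigma2_sire={self.sigma2_sire:.6g}  "
            f"sigma2_resid={self.sigma2_resid:.6g}  "
            f"REML loglik={self.reml_loglik:.4f}",
            "  coefficients:",
        ]
        for name, b, s in zip(self.x_names, self.beta, self.se_beta):
            lines.append(f"    {name:<24s} {b:>12.5g}  (SE {s:.5g})")
        return "\n".join(lines)


def _dummy_code(series: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    # reference level = first lexicographic level, for determinism
    levels = sorted(pd.unique(series.astype(str)))
    if len(levels) < 2:
        raise ModelSpecificationError(
            f"factor '{prefix}' has a single level ({levels}); "
            "it cannot enter the model"
        )
    cols = [(series.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
    names = [f"{prefix}[{lv}]" for lv in levels[1:]]
    return np.column_stack(cols), names


def build_design(
    meta: pd.DataFrame,
    covariates: pd.DataFrame | dict[str, np.ndarray] | None = None,
    fixed_factors: tuple[str, ...] = ("breed", "pen"),
    random_factor: str = "sire",
    numeric: tuple[str, ...] = ("age",),
) -> DesignMatrices:
    """Build fixed (X) and random (Z) design matrices from herd metadata.

    X holds an intercept, reference-coded dummies for ``fixed_factors``,
    the ``numeric`` metadata columns, and any extra ``covariates``.  Columns
    that are numerically linearly dependent on earlier ones (checked by a
    rank-revealing QR sweep, the SVD-based dependency check) are dropped and
    recorded in ``dropped_columns``; all-constant covariates are likewise
    dropped with a warning entry rather than raising.  Z one-hot codes
    ``random_factor``.
    """
    if meta.isna().any().any():
        raise ModelSpecificationError("metadata contains missing values")
    n = len(meta)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["Intercept"]
    for fac in fixed_factors:
        mat, nm = _dummy_code(meta[fac], fac)
        blocks.append(mat)
        names.extend(nm)
    for col in numeric:
        blocks.append(meta[col].to_numpy(float).reshape(-1, 1))
        names.append(col)
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for col in cov.columns:
            v = cov[col].to_numpy(float)
            if not np.all(np.isfinite(v)):
                raise ModelSpecificationError(f"covariate '{col}' is non-finite")
            blocks.append(v.reshape(-1, 1))
            names.append(str(col))

    X_full = np.hstack(blocks)
    # greedy rank check: keep a column iff it increases numerical rank
    kept_idx: list[int] = []
    dropped: list[str] = []
    kept_mat = np.empty((n, 0))
    for j in range(X_full.shape[1]):
        cand = np.column_stack([kept_mat, X_full[:, j]])
        if np.linalg.matrix_rank(cand, tol=None) > kept_mat.shape[1]:
            kept_mat = cand
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    X = X_full[:, kept_idx]
    x_names = [names[j] for j in kept_idx]

    sire_levels = sorted(pd.unique(meta[random_factor].astype(str)))
    if len(sire_levels) < 2:
        raise ModelSpecificationError(
            f"random factor '{random_factor}' has fewer than 2 levels"
        )
    Z = np.column_stack(
        [(meta[random_factor].astype(str) == lv).to_numpy(float) for lv in sire_levels]
    )
    return DesignMatrices(
        X=X,
        Z=Z,
        x_names=x_names,
        z_names=[f"{random_factor}[{lv}]" for lv in sire_levels],
        rank=X.shape[1],
        dropped_columns=dropped,
    )


def _criterion_parts(
    lam: float, d: DesignMatrices, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """GLS pieces at variance ratio lam, shared across response columns.

    Returns (beta (p,G), rss (G,), logdet_H, logdet_XtHiX) where
    H = I + lam ZZ' and weighting is H^{-1}.
    """
    X = d.X
    Uz, sz2 = d.z_svd()
    # H^{-1} = I - Uz diag(lam sz2/(1+lam sz2)) Uz'
    shrink = lam * sz2 / (1.0 + lam * sz2)
    UtX = Uz.T @ X
    UtY = Uz.T @ Y
    XtHiX = X.T @ X - UtX.T @ (shrink[:, None] * UtX)
    XtHiY = X.T @ Y - UtX.T @ (shrink[:, None] * UtY)
    beta = np.linalg.solve(XtHiX, XtHiY)
    resid = Y - X @ beta
    Utr = Uz.T @ resid
    rss = np.einsum("ij,ij->j", resid, resid) - np.einsum(
        "ij,ij->j", Utr, shrink[:, None] * Utr
    )
    logdet_H = float(np.sum(np.log1p(lam * sz2)))
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'H^{-1}X not positive definite")
    return beta, np.maximum(rss, 1e-300), logdet_H, float(logdet_XtHiX)


def _profiled_negloglik(lam: np.ndarray, d: DesignMatrices, Y: np.ndarray) -> np.ndarray:
    """-2 * profiled REML log-likelihood per column of Y, shared lambdas.

    Shape: (len(lam), G).  sigma2_e is profiled out analytically.
    """
    df = d.n - d.p
    out = np.empty((len(lam), Y.shape[1]))
    for i, lm in enumerate(np.atleast_1d(lam)):
        _, rss, ldH, ldX = _criterion_parts(float(lm), d, Y)
        sigma2 = rss / df
        out[i] = df * np.log(2.0 * np.pi * sigma2) + df + ldH + ldX
    return out


def _perlam_solve(
    lams: np.ndarray, d: DesignMatrices, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched GLS with a distinct lambda per column of Y.

    Returns (beta (p,G), rss (G,), logdet_H (G,), logdet_XtHiX (G,)).
    """
    X = d.X
    Uz, sz2 = d.z_svd()
    G = Y.shape[1]
    shrink = (lams[None, :] * sz2[:, None]) / (1.0 + lams[None, :] * sz2[:, None])
    UtX = Uz.T @ X          # (q, p)
    UtY = Uz.T @ Y          # (q, G)
    XtX = X.T @ X
    XtY = X.T @ Y
    # per-gene normal matrices: XtX - UtX' diag(shrink_g) UtX
    corr = np.einsum("qi,qg,qj->gij", UtX, shrink, UtX, optimize=True)
    A = XtX[None, :, :] - corr                      # (G, p, p)
    rhs = XtY.T - np.einsum("qi,qg,qg->gi", UtX, shrink, UtY, optimize=True)
    beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0].T   # (p, G)
    resid = Y - X @ beta
    Utr = Uz.T @ resid
    rss = np.einsum("ng,ng->g", resid, resid) - np.einsum(
        "qg,qg->g", shrink * Utr, Utr
    )
    logdet_H = np.sum(np.log1p(lams[None, :] * sz2[:, None]), axis=0)
    sign, logdet_A = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("X'H^{-1}X not positive definite")
    return beta, np.maximum(rss, 1e-300), logdet_H, logdet_A


def _perlam_negloglik(lams: np.ndarray, d: DesignMatrices, Y: np.ndarray) -> np.ndarray:
    """-2 * profiled REML criterion with per-column lambdas. Shape (G,)."""
    df = d.n - d.p
    _, rss, ldH, ldA = _perlam_solve(lams, d, Y)
    return df * np.log(2.0 * np.pi * rss / df) + df + ldH + ldA


def reml_loglik_at(
    y: np.ndarray, d: DesignMatrices, sigma2_s: float, sigma2_e: float
) -> float:
    """REML log-likelihood at explicit variance components (for oracles).

    Evaluates the unprofiled criterion with beta set to its GLS value at
    ``V = sigma2_e I + sigma2_s ZZ'``.
    """
    if sigma2_e <= 0 or sigma2_s < 0:
        raise ValueError("need sigma2_e > 0 and sigma2_s >= 0")
    Y = np.asarray(y, float).reshape(-1, 1)
    lam = sigma2_s / sigma2_e
    _, rss, ldH, ldX = _criterion_parts(lam, d, Y)
    n, p = d.n, d.p
    # log|V| = n log sigma2_e + log|H|; log|X'V^-1 X| = log|X'H^-1 X| - p log sigma2_e
    val = (
        (n - p) * np.log(2.0 * np.pi)
        + n * np.log(sigma2_e)
        + ldH
        + ldX
        - p * np.log(sigma2_e)
        + rss[0] / sigma2_e
    )
    return float(-0.5 * val)


def _finish_fit(
    lam: float, d: DesignMatrices, y: np.ndarray, converged: bool
) -> LMMFit:
    n, p = d.n, d.p
    df = n - p
    Y = y.reshape(-1, 1)
    beta, rss, ldH, ldX = _criterion_parts(lam, d, Y)
    beta = beta[:, 0]
    sigma2_e = float(rss[0] / df)
    sigma2_s = float(lam * sigma2_e)
    # u = lam Z' H^{-1} (y - X beta)
    Uz, sz2 = d.z_svd()
    shrink = lam * sz2 / (1.0 + lam * sz2)
    r_marg = y - d.X @ beta
    Hi_r = r_marg - Uz @ (shrink * (Uz.T @ r_marg))
    u = lam * (d.Z.T @ Hi_r)
    # Var(beta) = sigma2_e (X' H^-1 X)^-1
    UtX = Uz.T @ d.X
    XtHiX = d.X.T @ d.X - UtX.T @ (shrink[:, None] * UtX)
    cov_beta = sigma2_e * np.linalg.inv(XtHiX)
    se_beta = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    fitted_marg = d.X @ beta
    fitted_cond = fitted_marg + d.Z @ u
    loglik = -0.5 * (
        df * np.log(2.0 * np.pi) + df + df * np.log(sigma2_e) + ldH + ldX
    )
    return LMMFit(
        beta=beta,
        se_beta=se_beta,
        u=u,
        sigma2_sire=sigma2_s,
        sigma2_resid=sigma2_e,
        fitted_marginal=fitted_marg,
        fitted_conditional=fitted_cond,
        resid_conditional=y - fitted_cond,
        reml_loglik=float(loglik),
        converged=converged,
        x_names=list(d.x_names),
        z_names=list(d.z_names),
        n=n,
        rank_x=d.rank,
    )


def _grid_lambdas() -> np.ndarray:
    grid = np.concatenate(
        [[0.0], np.logspace(_LOG_LAM_LO, _LOG_LAM_HI, _N_GRID)]
    )
    return grid


def _golden_refine(
    d: DesignMatrices, Y: np.ndarray, lo: np.ndarray, hi: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Vectorised golden-section minimisation of the profiled criterion.

    ``lo``/``hi`` are per-column brackets on lambda.  Returns per-column
    lambda and a convergence flag (bracket shrunk below tol).
    """

    a, b = lo.copy(), hi.copy()
    c = b - _GOLDEN * (b - a)
    e = a + _GOLDEN * (b - a)
    fc = _perlam_negloglik(c, d, Y)
    fe = _perlam_negloglik(e, d, Y)
    max_iter = 80
    for _ in range(max_iter):
        if np.all(b - a < tol * np.maximum(1.0, b)):
            break
        left = fc < fe
        b = np.where(left, e, b)
        a = np.where(left, a, c)
        c_new = b - _GOLDEN * (b - a)
        e_new = a + _GOLDEN * (b - a)
        # one interior point carries over per side; evaluate only the other
        fc_old, fe_old = fc, fe
        fc = np.where(left, np.nan, fe_old)
        fe = np.where(left, fc_old, np.nan)
        need_c = np.isnan(fc)
        need_e = np.isnan(fe)
        if need_c.any():
            fc[need_c] = _perlam_negloglik(c_new[need_c], d, Y[:, need_c])
        if need_e.any():
            fe[need_e] = _perlam_negloglik(e_new[need_e], d, Y[:, need_e])
        c, e = c_new, e_new
    converged = bool(np.all(b - a < tol * np.maximum(1.0, b)))
    lam = 0.5 * (a + b)
    return lam, converged


def fit_reml(y: np.ndarray, d: DesignMatrices) -> LMMFit:
    """Fit the mixed model by REML, profiling the variance ratio.

    The profiled criterion is evaluated on ``{0} ∪ logspace(1e-6, 1e3, 61)``
    and refined by golden section around the grid optimum.  A boundary
    optimum at lambda = 0 returns the exact OLS solution with
    ``sigma2_sire = 0``.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if y.shape[0] != d.n:
        raise ValueError("response length does not match design rows")
    if d.n < d.p + 2:
        raise ValueError("need at least rank(X) + 2 observations")
    Y = y.reshape(-1, 1)
    grid = _grid_lambdas()
    crit = _profiled_negloglik(grid, d, Y)[:, 0]
    k = int(np.argmin(crit))
    if k == 0:
        # boundary: check whether a tiny positive lambda improves; if not, OLS
        return _finish_fit(0.0, d, y, converged=True)
    lo = grid[k - 1]
    hi = grid[min(k + 1, len(grid) - 1)]
    lam, conv = _golden_refine(d, Y, np.array([lo]), np.array([hi]))
    lam_star = float(lam[0])
    # guard: refined point must not be worse than the grid point
    if _profiled_negloglik(np.array([lam_star]), d, Y)[0, 0] > crit[k]:
        lam_star, conv = float(grid[k]), False
    return _finish_fit(lam_star, d, y, converged=conv)


def fit_reml_batch(Y: np.ndarray, d: DesignMatrices) -> dict[str, np.ndarray]:
    """REML fits for every column of ``Y`` sharing one design.

    Grid search is vectorised across columns; golden-section refinement runs
    with per-column brackets.  Returns arrays: ``lam``, ``sigma2_sire``,
    ``sigma2_resid``, ``beta`` (p×G), ``resid_conditional`` (n×G),
    ``fitted_conditional`` (n×G).
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[0] != d.n:
        raise ValueError("Y must be n × G")
    if not np.all(np.isfinite(Y)):
        raise ValueError("response matrix contains non-finite values")
    n, p = d.n, d.p
    df = n - p
    grid = _grid_lambdas()
    crit = _profiled_negloglik(grid, d, Y)  # (n_grid, G)
    k = np.argmin(crit, axis=0)
    lam = np.where(k == 0, 0.0, np.nan)
    interior = k > 0
    if interior.any():
        lo = grid[np.maximum(k - 1, 0)]
        hi = grid[np.minimum(k + 1, len(grid) - 1)]
        lam_ref = np.full(Y.shape[1], 0.0)
        lam_sub, _ = _golden_refine(
            d, Y[:, interior], lo[interior], hi[interior]
        )
        lam_ref[interior] = lam_sub
        lam = np.where(interior, lam_ref, 0.0)
    else:
        lam = np.zeros(Y.shape[1])

    # final pass with the per-column optima
    Uz, sz2 = d.z_svd()
    beta, rss, _, _ = _perlam_solve(lam, d, Y)
    sigma2_e = rss / df
    r_marg = Y - d.X @ beta
    shrink = (lam[None, :] * sz2[:, None]) / (1.0 + lam[None, :] * sz2[:, None])
    Hi_r = r_marg - Uz @ (shrink * (Uz.T @ r_marg))
    u = lam[None, :] * (d.Z.T @ Hi_r)
    fitted_cond = d.X @ beta + d.Z @ u
    resid_cond = Y - fitted_cond
    return {
        "lam": lam,
        "sigma2_sire": lam * sigma2_e,
        "sigma2_resid": sigma2_e,
        "beta": beta,
        "fitted_conditional": fitted_cond,
        "resid_conditional": resid_cond,
    }


def wald_p(fit: LMMFit, coef_name: str) -> float:
    """Two-sided Wald p-value for one fixed coefficient.

    Uses t = beta / SE with n − rank(X) denominator degrees of freedom, a
    deliberately simple df rule (no Satterthwaite correction).
    """
    if coef_name not in fit.x_names:
        raise AliasedCoefficientError(
            f"coefficient '{coef_name}' is not in the retained design "
            f"(retained: {fit.x_names})"
        )
    b = fit.coef(coef_name)
    s = fit.se(coef_name)
    if b == 0.0:
        return 1.0
    df = fit.n - fit.rank_x
    t = b / s
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def model_r2(fit: LMMFit, y: np.ndarray) -> float:
    """Squared Pearson correlation of y with the conditional fitted values."""
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ValueError("R² undefined for zero-variance response")
    f = fit.fitted_conditional
    if np.std(f) == 0:
        return 0.0
    r = np.corrcoef(y, f)[0, 1]
    return float(r * r)


def marginal_r2(fit: LMMFit, y: np.ndarray) -> float:
    """Squared correlation of y with the fixed-effect (marginal) fit only."""
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ValueError("R² undefined for zero-variance response")
    f = fit.fitted_marginal
    if np.std(f) == 0:
        return 0.0
    r = np.corrcoef(y, f)[0, 1]
    return float(r * r)
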