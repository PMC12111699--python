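"""Mixed-model engine: design construction, REML correctness, Wald tests.

Oracles: ordinary least squares at the zero-variance boundary, a brute-force
grid over both variance components, and lme4's lmer (run through Rscript on
one small fixture) as an independent reference implementation.
"""

from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from bloodtraits.mixedmodel import (
    AliasedCoefficientError,
    ModelSpecificationError,
    build_design,
    fit_reml,
    fit_reml_batch,
    marginal_r2,
    model_r2,
    reml_loglik_at,
    wald_p,
)
from bloodtraits.synthetic_data import GroundTruth, SimConfig, simulate_herd


def _simulated_response(meta, rng, beta_x=0.0, sigma_s=0.1, sigma_e=0.2, x=None):
    sires = sorted(meta["sire"].unique())
    u = rng.normal(0.0, sigma_s, len(sires))
    idx = [sires.index(s) for s in meta["sire"]]
    y = 1.0 + 0.002 * meta["age"].to_numpy(float) + u[idx]
    if x is not None:
        y = y + beta_x * x
    return y + rng.normal(0.0, sigma_e, len(meta))


class TestBuildDesign:
    def test_column_count_no_aliasing(self, herd_meta, rng):
        d = build_design(herd_meta, covariates={"cov": rng.normal(size=len(herd_meta))})
        # intercept + 2 breed + 3 pen + age + cov
        assert d.X.shape[1] == 8
        assert d.rank == 8
        assert d.dropped_columns == []

    def test_z_one_hot(self, herd_meta):
        d = build_design(herd_meta)
        assert d.Z.shape[1] == 12
        np.testing.assert_array_equal(d.Z.sum(axis=1), 1.0)
        assert set(np.unique(d.Z)) <= {0.0, 1.0}

    def test_aliased_factor_dropped(self, herd_meta):
        meta = herd_meta.copy()
        meta["pen"] = meta["breed"].str.replace("B", "P")  # same partition
        d = build_design(meta)
        assert len(d.dropped_columns) == 2  # both non-reference pen dummies
        assert np.linalg.matrix_rank(d.X) == d.X.shape[1]

    def test_constant_covariate_dropped_not_error(self, herd_meta):
        d = build_design(herd_meta, covariates={"flat": np.ones(len(herd_meta))})
        assert "flat" in d.dropped_columns
        assert "flat" not in d.x_names

    def test_single_level_factor_errors(self, herd_meta):
        meta = herd_meta.copy()
        meta["breed"] = "B1"
        with pytest.raises(ModelSpecificationError):
            build_design(meta)


class TestFitREML:
    def test_zero_sire_variance_reduces_to_ols(self, herd_meta, rng):
        # all sires identical: REML should land on the boundary and match OLS
        y = _simulated_response(herd_meta, rng, sigma_s=0.0)
        d = build_design(herd_meta)
        fit = fit_reml(y, d)
        beta_ols, *_ = np.linalg.lstsq(d.X, y, rcond=None)
        assert fit.sigma2_sire < 1e-4
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-6, atol=1e-8)

    def test_boundary_fit_is_exactly_ols(self, herd_meta, rng):
        # force the boundary by fitting a response with no sire structure and
        # verifying the lambda=0 path: residuals orthogonal to X
        y = _simulated_response(herd_meta, rng, sigma_s=0.0, sigma_e=0.05)
        d = build_design(herd_meta)
        fit = fit_reml(y, d)
        if fit.sigma2_sire == 0.0:
            np.testing.assert_allclose(
                d.X.T @ fit.resid_conditional, 0.0, atol=1e-8
            )

    def test_reml_beats_brute_force_grid(self, rng):
        # n=40 instances: the profiled optimum must dominate a 50x50 grid
        cfg = SimConfig(seed=21, n_animals=40, n_sires=8, n_breeds=2, n_pens=2)
        meta = simulate_herd(cfg)
        for trial in range(3):
            y = _simulated_response(meta, rng, sigma_s=0.12, sigma_e=0.2)
            d = build_design(meta)
            fit = fit_reml(y, d)
            s2e_grid = np.geomspace(fit.sigma2_resid / 10, fit.sigma2_resid * 10, 50)
            s2s_grid = np.geomspace(1e-6, max(fit.sigma2_sire * 10, 1.0), 50)
            best = max(
                reml_loglik_at(y, d, s2s, s2e)
                for s2s in s2s_grid
                for s2e in s2e_grid
            )
            assert fit.reml_loglik >= best - 1e-6

    def test_variance_component_recovery(self):
        # n=2000, true (0.01, 0.03): averaged over 20 seeds within 25% rel.
        s2s_hat, s2e_hat = [], []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_animals=2000, n_sires=100, n_pens=4)
            meta = simulate_herd(cfg)
            r = np.random.default_rng(1000 + seed)
            y = _simulated_response(
                meta, r, sigma_s=np.sqrt(0.01), sigma_e=np.sqrt(0.03)
            )
            fit = fit_reml(y, build_design(meta))
            s2s_hat.append(fit.sigma2_sire)
            s2e_hat.append(fit.sigma2_resid)
        assert abs(np.mean(s2s_hat) - 0.01) / 0.01 < 0.25
        assert abs(np.mean(s2e_hat) - 0.03) / 0.03 < 0.25

    def test_residual_plus_fitted_is_y(self, herd_meta, rng):
        y = _simulated_response(herd_meta, rng)
        fit = fit_reml(y, build_design(herd_meta))
        np.testing.assert_allclose(
            fit.fitted_conditional + fit.resid_conditional, y, rtol=0, atol=1e-12
        )

    def test_permutation_equivariance(self, herd_meta, rng):
        y = _simulated_response(herd_meta, rng)
        perm = rng.permutation(len(herd_meta))
        fit1 = fit_reml(y, build_design(herd_meta))
        meta_p = herd_meta.iloc[perm].reset_index(drop=True)
        fit2 = fit_reml(y[perm], build_design(meta_p))
        np.testing.assert_allclose(
            fit2.resid_conditional, fit1.resid_conditional[perm], atol=1e-8
        )

    def test_batch_matches_single(self, herd_meta, rng):
        d = build_design(herd_meta)
        Y = np.column_stack(
            [_simulated_response(herd_meta, rng, sigma_s=s) for s in (0.0, 0.1, 0.3)]
        )
        batch = fit_reml_batch(Y, d)
        for j in range(Y.shape[1]):
            single = fit_reml(Y[:, j], d)
            np.testing.assert_allclose(
                batch["resid_conditional"][:, j],
                single.resid_conditional,
                atol=1e-6,
            )
            np.testing.assert_allclose(
                batch["sigma2_resid"][j], single.sigma2_resid, rtol=1e-4
            )

    def test_nonfinite_response_rejected(self, herd_meta):
        d = build_design(herd_meta)
        y = np.zeros(len(herd_meta))
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_reml(y, d)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
class TestAgainstLmer:
    def test_matches_lme4_reference(self, herd_meta, tmp_path):
        rng = np.random.default_rng(99)
        x = rng.normal(size=len(herd_meta))
        y = _simulated_response(herd_meta, rng, beta_x=0.3, x=x)
        d = build_design(herd_meta, covariates={"x": x})
        fit = fit_reml(y, d)
        df = herd_meta.copy()
        df["y"], df["x"] = y, x
        csv = tmp_path / "lmm.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(y ~ breed + pen + age + x + (1|sire), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        cat(vc$vcov[1], vc$vcov[2], fixef(m)["x"],
            sqrt(diag(vcov(m)))[which(names(fixef(m)) == "x")],
            logLik(m), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        s2s, s2e, bx, sex, ll = (float(v) for v in out.stdout.split())
        np.testing.assert_allclose(fit.sigma2_sire, s2s, rtol=1e-4, atol=1e-8)
        np.testing.assert_allclose(fit.sigma2_resid, s2e, rtol=1e-4)
        np.testing.assert_allclose(fit.coef("x"), bx, rtol=1e-5)
        np.testing.assert_allclose(fit.se("x"), sex, rtol=1e-4)
        np.testing.assert_allclose(fit.reml_loglik, ll, rtol=1e-5)


class TestWaldP:
    def test_p_is_one_at_zero_beta(self, herd_meta, rng):
        y = _simulated_response(herd_meta, rng)
        x = rng.normal(size=len(herd_meta))
        d = build_design(herd_meta, covariates={"x": x})
        fit = fit_reml(y, d)
        fit.beta[fit.x_names.index("x")] = 0.0
        assert wald_p(fit, "x") == 1.0

    def test_matches_ols_t_test_at_boundary(self, herd_meta, rng):
        from scipy import stats

        y = _simulated_response(herd_meta, rng, sigma_s=0.0)
        x = rng.normal(size=len(herd_meta))
        d = build_design(herd_meta, covariates={"x": x})
        fit = fit_reml(y, d)
        if fit.sigma2_sire == 0.0:
            XtXi = np.linalg.inv(d.X.T @ d.X)
            beta = XtXi @ d.X.T @ y
            resid = y - d.X @ beta
            df = len(y) - d.X.shape[1]
            s2 = resid @ resid / df
            j = d.x_names.index("x")
            t = beta[j] / np.sqrt(s2 * XtXi[j, j])
            p_ols = 2 * stats.t.sf(abs(t), df)
            np.testing.assert_allclose(wald_p(fit, "x"), p_ols, rtol=1e-8)

    def test_type_i_error_calibrated(self, herd_meta):
        # covariate independent of y: empirical rejection at 0.05 in [0.03, 0.07]
        d_base = None
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            r = np.random.default_rng(5000 + rep)
            y = _simulated_response(herd_meta, r, sigma_s=0.1)
            x = r.normal(size=len(herd_meta))
            d = build_design(herd_meta, covariates={"x": x})
            fit = fit_reml(y, d)
            rejections += wald_p(fit, "x") < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_dropped_coefficient_raises(self, herd_meta, rng):
        y = _simulated_response(herd_meta, rng)
        d = build_design(herd_meta, covariates={"flat": np.ones(len(herd_meta))})
        fit = fit_reml(y, d)
        with pytest.raises(AliasedCoefficientError):
            wald_p(fit, "flat")


class TestModelR2:
    def test_perfect_fit(self, herd_meta):
        d = build_design(herd_meta)
        y = d.X @ np.arange(1.0, d.X.shape[1] + 1.0)
        fit = fit_reml(y, d)
        assert model_r2(fit, y) > 1 - 1e-8

    def test_null_r2_small(self):
        cfg = SimConfig(seed=31, n_animals=1000, n_sires=40)
        meta = simulate_herd(cfg)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(7000 + seed)
            y = r.normal(size=1000)  # independent of every predictor
            fit = fit_reml(y, build_design(meta))
            hits += model_r2(fit, y) < 0.05
        assert hits >= 19

    def test_r2_increases_with_true_covariate(self, rng):
        cfg = SimConfig(seed=32, n_animals=300, n_sires=15)
        meta = simulate_herd(cfg)
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(8000 + seed)
            x = r.normal(size=300)
            y = _simulated_response(meta, r, beta_x=0.3, x=x)
            base = fit_reml(y, build_design(meta))
            full = fit_reml(y, build_design(meta, covariates={"x": x}))
            wins += model_r2(full, y) >= model_r2(base, y)
        assert wins == 20

    def test_zero_variance_y_signalled(self, herd_meta):
        d = build_design(herd_meta)
        y = np.linspace(0, 1, len(herd_meta))
        fit = fit_reml(y, d)
        with pytest.raises(ValueError):
            model_r2(fit, np.ones(len(herd_meta)))

    def test_marginal_r2_not_above_conditional(self, herd_meta, rng):
        y = _simulated_response(herd_meta, rng, sigma_s=0.3)
        fit = fit_reml(y, build_design(herd_meta))
        assert marginal_r2(fit, y) <= model_r2(fit, y) + 1e-6
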