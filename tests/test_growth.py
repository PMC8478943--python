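"""Growth-model estimation: oracle likelihood equivalence, degenerate cases,
variance decomposition and the slope-variation likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest

from trimtrack import (GrowthModelError, GrowthModelFit, ValidationError,
                       compare_models, fit_growth_model, loglik_direct,
                       variance_components)
from trimtrack.growth import LAMBDA

from conftest import growth_sim_config
from trimtrack import aggregate_trimesters, simulate_cohort


def make_matrix(Y, age=None, origin=None):
    df = pd.DataFrame(Y, columns=["value_t1", "value_t2", "value_t3"])
    df["age"] = age if age is not None else 30.0
    df["origin"] = origin if origin is not None else "EUR"
    return df


def test_profiled_loglik_matches_direct_mvn_evaluation(rng):
    """The sufficient-statistic objective equals a brute-force per-row
    multivariate-normal log-density at the returned parameters (n = 40)."""
    lat = rng.multivariate_normal([5.0, 1.0], [[1.0, 0.1], [0.1, 0.3]], size=40)
    Y = lat[:, [0]] + lat[:, [1]] * np.arange(3.0) + rng.normal(0, 0.7, (40, 3))
    age = rng.normal(30, 5, 40)
    origin = rng.choice(["EUR", "AFR"], 40)
    m = make_matrix(Y, age, origin)
    fit = fit_growth_model(m, covariates=("age", "origin"))
    assert loglik_direct(fit, m, ("age", "origin")) == pytest.approx(
        fit.loglik, abs=1e-6)


def test_noiseless_lines_recover_exact_fit(rng):
    """Exactly linear per-woman data drive the residual variances to ~0 and
    reproduce each woman's intercept/slope by direct regression."""
    lat = rng.multivariate_normal([3.0, -1.0], [[2.0, 0.0], [0.0, 0.5]], size=80)
    Y = lat[:, [0]] + lat[:, [1]] * np.arange(3.0)
    m = make_matrix(Y)
    fit = fit_growth_model(m, covariates=(), compute_se=False)
    assert (fit.theta <= 1e-6).all()
    # per-woman latents recovered by regression on t agree with truth
    slope_hat = (Y[:, 2] - Y[:, 0]) / 2
    np.testing.assert_allclose(slope_hat, lat[:, 1], atol=1e-10)
    assert fit.psi[0, 0] == pytest.approx(np.var(lat[:, 0]), rel=0.05)


def test_zero_slope_truth_gives_boundary_fit(rng):
    cfg = growth_sim_config(n_women=800, psi11=0.0, psi01=0.0, seed=31)
    m = aggregate_trimesters(simulate_cohort(cfg), "PLATE")
    fit1 = fit_growth_model(m, covariates=(), compute_se=False)
    fit0 = fit_growth_model(m, covariates=(), model_kind="intercept_only",
                            compute_se=False)
    assert fit1.loglik >= fit0.loglik - 1e-6  # monotonicity
    assert fit1.psi[1, 1] < 0.1
    cmp_ = compare_models(fit0, fit1)
    assert cmp_.lrt < 10.0


def test_psi_returned_psd_across_fits():
    for seed in range(4):
        cfg = growth_sim_config(n_women=200, psi11=0.1, psi01=0.2, seed=seed)
        m = aggregate_trimesters(simulate_cohort(cfg), "PLATE")
        fit = fit_growth_model(m, covariates=(), compute_se=False)
        assert np.linalg.eigvalsh(fit.psi).min() >= -1e-10
        assert np.linalg.eigvalsh(fit.implied_cov).min() >= -1e-10


def test_parameter_recovery_single_cohort():
    cfg = growth_sim_config(n_women=1457, psi00=1.0, psi11=0.25, psi01=0.0,
                            theta=0.5, seed=77)
    m = aggregate_trimesters(simulate_cohort(cfg), "PLATE")
    fit = fit_growth_model(m, covariates=())
    assert fit.psi[0, 0] == pytest.approx(1.0, rel=0.2)
    assert fit.psi[1, 1] == pytest.approx(0.25, rel=0.3)
    assert fit.theta.mean() == pytest.approx(0.5, rel=0.2)
    assert fit.latent_means[0] == pytest.approx(10.0, abs=0.1)
    assert fit.latent_means[1] == pytest.approx(0.5, abs=0.05)
    assert fit.se.get("psi00", np.nan) > 0


def test_covariate_effect_recovered():
    cfg = growth_sim_config(n_women=2000, seed=41, age_effect=0.05)
    m = aggregate_trimesters(simulate_cohort(cfg), "PLATE")
    fit = fit_growth_model(m, covariates=("age",))
    # generator scales the age effect by sqrt(psi00)=1, so slope on age ~0.05
    assert fit.covariate_coeffs.loc["intercept", "age"] == pytest.approx(0.05, abs=0.02)


def test_requires_complete_data_and_minimum_n():
    m = make_matrix(np.ones((12, 3)))
    m.loc[0, "value_t2"] = np.nan
    with pytest.raises(ValidationError, match="complete"):
        fit_growth_model(m, covariates=())
    with pytest.raises(ValidationError, match="n >= 10"):
        fit_growth_model(make_matrix(np.random.default_rng(0).normal(size=(5, 3))),
                         covariates=())


class TestVarianceComponents:
    @staticmethod
    def manual_fit(psi00, psi11, psi01, theta):
        psi = np.array([[psi00, psi01], [psi01, psi11]])
        return GrowthModelFit(
            latent_means=(0.0, 0.0), psi=psi, theta=np.asarray(theta, float),
            covariate_coeffs=pd.DataFrame(np.zeros((2, 1)),
                                          index=["intercept", "slope"],
                                          columns=["const"]),
            loglik=0.0, n=100, model_kind="intercept_slope")

    def test_pure_intercept_closed_form(self):
        vc = variance_components(self.manual_fit(0.8, 0.0, 0.0, (0.2, 0.2, 0.2)))
        assert vc.repeatability == pytest.approx(0.8)
        assert vc.change == pytest.approx(0.0)
        assert vc.closure == pytest.approx(1.0, abs=1e-12)

    def test_no_between_woman_variance(self):
        vc = variance_components(self.manual_fit(0.0, 0.0, 0.0, (1.0, 1.0, 1.0)))
        assert vc.repeatability == 0.0 and vc.residual == pytest.approx(1.0)

    def test_slope_share_by_enumeration(self):
        """Components agree with direct enumeration of occasion variances
        psi00 + t^2 psi11 + 2 t psi01 + theta_t over t = 0, 1, 2."""
        psi00, psi11, psi01, th = 0.6, 0.3, 0.0, 0.4
        occ = [psi00 + t * t * psi11 + 2 * t * psi01 + th for t in (0, 1, 2)]
        pheno = float(np.mean(occ))
        vc = variance_components(self.manual_fit(psi00, psi11, psi01, (th,) * 3))
        assert vc.phenotypic_variance == pytest.approx(pheno)
        assert vc.repeatability == pytest.approx(psi00 / pheno)
        assert vc.change == pytest.approx(np.mean([0, 1, 4]) * psi11 / pheno)
        assert vc.closure == pytest.approx(1.0, abs=1e-12)

    def test_zero_phenotypic_variance_errors(self):
        with pytest.raises(ValidationError, match="positive"):
            variance_components(self.manual_fit(0.0, 0.0, 0.0, (0.0, 0.0, 0.0)))


class TestCompareModels:
    def test_identical_fits_give_zero_lrt_p_one(self, growth_matrix):
        fit0 = fit_growth_model(growth_matrix, covariates=(),
                                model_kind="intercept_only", compute_se=False)
        fit0b = GrowthModelFit(**{**fit0.__dict__, "model_kind": "intercept_slope"})
        cmp_ = compare_models(fit0, fit0b)
        assert cmp_.lrt == 0.0 and cmp_.p_naive == 1.0 and cmp_.p_boundary == 1.0

    def test_slope_model_detects_true_slope_variance(self, growth_matrix):
        fit1 = fit_growth_model(growth_matrix, covariates=(), compute_se=False)
        fit0 = fit_growth_model(growth_matrix, covariates=(),
                                model_kind="intercept_only", compute_se=False)
        cmp_ = compare_models(fit0, fit1)
        assert cmp_.p_naive < 0.001 and cmp_.significant
        assert cmp_.p_boundary <= cmp_.p_naive

    def test_wrong_nesting_order_errors(self, growth_matrix):
        fit1 = fit_growth_model(growth_matrix, covariates=(), compute_se=False)
        with pytest.raises(ValidationError):
            compare_models(fit1, fit1)

    def test_loglik_below_nested_is_optimizer_failure(self, growth_matrix):
        fit1 = fit_growth_model(growth_matrix, covariates=(), compute_se=False)
        fit0 = fit_growth_model(growth_matrix, covariates=(),
                                model_kind="intercept_only", compute_se=False)
        broken = GrowthModelFit(**{**fit1.__dict__, "loglik": fit0.loglik - 5.0})
        with pytest.raises(GrowthModelError):
            compare_models(fit0, broken)
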