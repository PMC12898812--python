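"""Mixed-logit estimation: oracle equivalences, indices, invariances."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
import statsmodels.api as sm

from ushape import (
    Dataset,
    FootRecord,
    GeneratorConfig,
    ModelSpec,
    fit_indices,
    fit_mixed_logistic,
    fit_null_model,
    generate_dataset,
    likelihood_ratio_test,
    predict_probability,
    write_table,
)
from ushape.errors import ComparisonError, SeparationError
from ushape.melogit import build_design, marginal_loglik

QUAD = ModelSpec(degree=2)


@pytest.fixture(scope="module")
def quad_fit(calibrated_dataset):
    return fit_mixed_logistic(calibrated_dataset, QUAD)


class TestAgainstPlainLogistic:
    def test_sigma_zero_data_recovers_glm(self, no_cluster_dataset):
        fit = fit_mixed_logistic(no_cluster_dataset, QUAD)
        X, y, codes, _, _ = build_design(no_cluster_dataset, QUAD)
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.sigma_u < 0.05
        rel = np.abs(fit.beta - oracle.params) / np.abs(oracle.params)
        assert rel.max() < 1e-4

    def test_marginal_likelihood_collapses_at_sigma_zero(
        self, no_cluster_dataset
    ):
        X, y, codes, _, _ = build_design(no_cluster_dataset, QUAD)
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        ll = marginal_loglik(np.asarray(oracle.params), 0.0, X, y, codes)
        assert ll == pytest.approx(oracle.llf, rel=1e-6)


class TestQuadrature:
    def test_node_count_stability(self, calibrated_dataset, quad_fit):
        X, y, codes, _, _ = build_design(calibrated_dataset, QUAD)
        ll15 = marginal_loglik(quad_fit.beta, quad_fit.sigma_u, X, y, codes, 15)
        ll25 = marginal_loglik(quad_fit.beta, quad_fit.sigma_u, X, y, codes, 25)
        assert abs(ll15 - ll25) / abs(ll15) < 1e-6

    def test_fast_laplace_close_to_agq(self, calibrated_dataset, quad_fit):
        # Laplace attenuates sigma_u (clusters of size 2 carry little
        # information), shifting mainly the intercept; slopes stay close
        fast = fit_mixed_logistic(calibrated_dataset, QUAD, fast=True,
                                  compute_vcov=False)
        assert np.abs(fast.beta - quad_fit.beta).max() < 0.15
        assert abs(fast.coef("ssndt2") - quad_fit.coef("ssndt2")) < 5e-3
        assert fast.loglik == pytest.approx(quad_fit.loglik, abs=0.5)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestAgainstGlmer:
    def test_matches_lme4_glmer(self, tmp_path, calibrated_dataset, quad_fit):
        """Independent oracle: lme4::glmer with 25-node quadrature."""
        csv = tmp_path / "d.csv"
        write_table(calibrated_dataset, csv)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$xc <- d$ssndt_mm - mean(d$ssndt_mm)
            d$lc <- d$load_h_per_week - mean(d$load_h_per_week)
            d$ec <- d$experience_years - mean(d$experience_years)
            m <- glmer(injured ~ xc + I(xc^2) + lc + ec +
                       (1|participant_id), data=d, family=binomial, nAGQ=25)
            cat(fixef(m), sqrt(unlist(VarCorr(m))),
                as.numeric(logLik(m)), sep="\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        beta_r, sigma_r, ll_r = np.array(vals[:5]), vals[5], vals[6]
        assert np.abs(quad_fit.beta - beta_r).max() < 1e-3
        assert quad_fit.sigma_u == pytest.approx(sigma_r, abs=5e-3)
        assert quad_fit.loglik == pytest.approx(ll_r, abs=1e-3)


class TestErrors:
    def test_one_class_outcome(self):
        recs = [
            FootRecord(f"p{i}", side, 5.0 + i, 0, 8.0, 4.0)
            for i in range(10)
            for side in ("left", "right")
        ]
        with pytest.raises(SeparationError):
            fit_mixed_logistic(Dataset(recs), QUAD)

    def test_mismatched_rows_comparison_error(self, calibrated_dataset,
                                              quad_fit):
        other = generate_dataset(GeneratorConfig(seed=99))
        null_other = fit_null_model(other)
        with pytest.raises(ComparisonError):
            fit_indices(quad_fit, null_other)


class TestFitIndices:
    def test_definitional_identities(self, calibrated_dataset, quad_fit):
        null = fit_null_model(calibrated_dataset)
        idx = fit_indices(quad_fit, null)
        k = len(quad_fit.beta) + 1
        assert idx.aic == pytest.approx(-2 * quad_fit.loglik + 2 * k)
        assert idx.bic == pytest.approx(
            -2 * quad_fit.loglik + k * np.log(quad_fit.n_obs)
        )
        assert idx.deviance == pytest.approx(-2 * quad_fit.loglik)
        n = quad_fit.n_obs
        cs = 1 - np.exp((2 / n) * (null.loglik - quad_fit.loglik))
        assert idx.nagelkerke_r2 == pytest.approx(
            cs / (1 - np.exp((2 / n) * null.loglik))
        )
        assert 0 <= idx.nagelkerke_r2 < 1

    def test_no_improvement_gives_zero_r2(self, calibrated_dataset):
        null = fit_null_model(calibrated_dataset)
        idx = fit_indices(null, null)
        assert idx.nagelkerke_r2 == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_beats_linear_on_u_shaped_data(self):
        ds = generate_dataset(
            GeneratorConfig(n_participants=500, true_beta2=0.08, seed=31)
        )
        null = fit_null_model(ds)
        f1 = fit_mixed_logistic(ds, ModelSpec(1), compute_vcov=False)
        f2 = fit_mixed_logistic(ds, ModelSpec(2), compute_vcov=False)
        assert fit_indices(f2, null).aic < fit_indices(f1, null).aic


class TestLikelihoodRatio:
    def test_self_comparison(self, quad_fit):
        stat, df, p = likelihood_ratio_test(quad_fit, quad_fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_statistic_identity_and_df(self, calibrated_dataset, quad_fit):
        f1 = fit_mixed_logistic(calibrated_dataset, ModelSpec(1),
                                compute_vcov=False)
        stat, df, p = likelihood_ratio_test(f1, quad_fit)
        assert stat == pytest.approx(2 * (quad_fit.loglik - f1.loglik))
        assert df == 1
        assert 0 <= p <= 1

    def test_non_nested_raises(self, calibrated_dataset, quad_fit):
        f_unadj = fit_mixed_logistic(
            calibrated_dataset, ModelSpec(3, adjust=False), compute_vcov=False
        )
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(quad_fit, f_unadj)

    def test_power_against_linear_under_strong_u(self):
        hits = 0
        for s in range(12):
            ds = generate_dataset(
                GeneratorConfig(n_participants=500, true_beta2=0.08,
                                seed=500 + s)
            )
            f1 = fit_mixed_logistic(ds, ModelSpec(1), compute_vcov=False)
            f2 = fit_mixed_logistic(ds, ModelSpec(2), compute_vcov=False)
            hits += likelihood_ratio_test(f1, f2)[2] < 0.05
        assert hits >= 11


class TestPredictAndInvariance:
    def test_centering_identity(self, quad_fit):
        p = predict_probability(
            quad_fit, quad_fit.centering["ssndt_mean"]
        )
        expected = 1 / (1 + np.exp(-quad_fit.coef("intercept")))
        assert p == pytest.approx(expected, rel=1e-12)

    def test_published_coefficients_at_mean(self):
        # logistic(-1.960) at the exposure mean with covariates at means
        assert 1 / (1 + np.exp(1.960)) == pytest.approx(0.1235, abs=5e-4)

    def test_monotone_away_from_minimum(self, quad_fit):
        from ushape import minimum_risk_point

        x_min = minimum_risk_point(quad_fit).x_min_mm
        right = predict_probability(quad_fit, x_min + np.array([0, 1, 2, 4]))
        left = predict_probability(quad_fit, x_min - np.array([0, 1, 2, 4]))
        assert (np.diff(right) > 0).all() and (np.diff(left) > 0).all()

    def test_shift_invariance_with_centering(self, no_cluster_dataset):
        fit = fit_mixed_logistic(no_cluster_dataset, QUAD,
                                 compute_vcov=False)
        shifted = Dataset(
            [
                FootRecord(r.participant_id, r.foot_side, r.ssndt_mm + 3.7,
                           r.injured, r.load_h_per_week, r.experience_years)
                for r in no_cluster_dataset.records
            ]
        )
        fit2 = fit_mixed_logistic(shifted, QUAD, compute_vcov=False)
        assert np.abs(fit.beta - fit2.beta).max() < 1e-6
        assert abs(fit.loglik - fit2.loglik) < 1e-8
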