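"""Random-intercept logistic regression: oracles, invariances, inference."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from discountkit.exceptions import ValidationError
from discountkit.glmm import (
    GlmmFit,
    ModelSpec,
    fit_multilevel_logistic,
    icc,
    likelihood_ratio_test,
    marginal_loglik,
    wald_summary,
)
from discountkit.synthdata import CohortConfig, generate_cohort

SPEC = ModelSpec()


def make_fit(beta, se, names=("x",)):
    """Bare GlmmFit for exercising the Wald conventions."""
    return GlmmFit(
        names=names,
        beta=np.atleast_1d(np.asarray(beta, float)),
        se=np.atleast_1d(np.asarray(se, float)),
        sigma2_u=0.0,
        loglik=0.0,
        n_obs=0,
        n_groups=0,
        group_levels=(),
        u_modes=np.zeros(0),
    )


class TestDegenerateAndOracles:
    def test_zero_variance_cohort_reduces_to_pooled_logistic(self):
        """With no country heterogeneity the fit must equal plain logistic ML."""
        sm = pytest.importorskip("statsmodels.api")
        cohort = generate_cohort(
            CohortConfig(n_participants=800, country_intercept_sd=0.0, seed=2)
        )
        fit = fit_multilevel_logistic(cohort.participants, SPEC)
        assert fit.boundary and fit.sigma2_u == 0.0
        X = sm.add_constant(cohort.participants[list(SPEC.fixed)])
        pooled = sm.Logit(cohort.participants["vaccinated"], X).fit(disp=0)
        assert np.allclose(fit.beta, pooled.params.to_numpy(), atol=1e-6)
        assert np.allclose(fit.se, pooled.bse.to_numpy(), atol=1e-6)

    def test_laplace_agrees_with_gauss_hermite_quadrature(self):
        cohort = generate_cohort(CohortConfig(n_participants=500, seed=1))
        fit = fit_multilevel_logistic(cohort.participants, SPEC)
        ll_agq = marginal_loglik(
            cohort.participants, SPEC, fit.beta, fit.sigma2_u, method="agq", n_nodes=15
        )
        assert abs(ll_agq - fit.loglik) < 0.1

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agreement_with_lme4_glmer(self, tmp_path):
        """Independent oracle: the reference Laplace GLMM implementation."""
        cohort = generate_cohort(CohortConfig(n_participants=400, seed=7))
        data_path = tmp_path / "cohort.csv"
        cohort.participants.to_csv(data_path, index=False)
        script = f"""
        d <- read.csv("{data_path}")
        suppressMessages(library(lme4))
        m <- glmer(vaccinated ~ age + education + income + essential_worker +
                   distress_index + auc + (1 | country), data = d, family = binomial)
        out <- list(beta = unname(fixef(m)), se = unname(coef(summary(m))[, 2]),
                    sigma2 = unname(VarCorr(m)$country[1]), loglik = as.numeric(logLik(m)))
        cat(jsonlite::toJSON(out, digits = 12))
        """
        r = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert r.returncode == 0, r.stderr
        ref = json.loads(r.stdout)
        fit = fit_multilevel_logistic(cohort.participants, SPEC)
        assert np.allclose(fit.beta, ref["beta"], atol=5e-3)
        assert np.allclose(fit.se, ref["se"], rtol=0.02)
        assert fit.sigma2_u == pytest.approx(ref["sigma2"][0], abs=0.01)
        assert fit.loglik == pytest.approx(ref["loglik"][0], abs=0.01)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(n_participants=800, seed=5)).participants


class TestInvariances:
    def test_shifting_a_predictor_moves_only_the_intercept(self, cohort):
        base = fit_multilevel_logistic(cohort, SPEC)
        shifted = cohort.copy()
        shifted["age"] = shifted["age"] + 50.0
        fit = fit_multilevel_logistic(shifted, SPEC)
        assert np.allclose(fit.beta[1:], base.beta[1:], atol=1e-6)
        assert fit.beta[0] == pytest.approx(base.beta[0] - 50.0 * base.beta[1], abs=1e-6)

    def test_scaling_a_predictor_inversely_scales_its_coefficient(self, cohort):
        base = fit_multilevel_logistic(cohort, SPEC)
        scaled = cohort.copy()
        scaled["age"] = scaled["age"] * 10.0
        fit = fit_multilevel_logistic(scaled, SPEC)
        assert fit.beta[1] * 10.0 == pytest.approx(base.beta[1], abs=5e-7)
        assert fit.sigma2_u == pytest.approx(base.sigma2_u, abs=1e-6)


class TestIcc:
    @pytest.mark.parametrize(
        "sigma2, expected",
        [(0.0, 0.0), (np.pi**2 / 3, 0.5), (1.54, 1.54 / (1.54 + np.pi**2 / 3))],
    )
    def test_closed_form(self, sigma2, expected):
        assert icc(sigma2) == pytest.approx(expected, abs=1e-12)

    def test_reference_variance_rounds_to_0_319(self):
        assert round(icc(1.54), 3) == 0.319

    def test_negative_variance_rejected(self):
        with pytest.raises(ValidationError):
            icc(-0.1)


class TestLikelihoodRatioTest:
    def test_identical_models_give_zero(self, small_cohort):
        fit = fit_multilevel_logistic(small_cohort.participants, SPEC)
        chi2, df, p = likelihood_ratio_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_default_spec_drops_six_fixed_effects(self, small_cohort):
        full = fit_multilevel_logistic(small_cohort.participants, SPEC)
        null = fit_multilevel_logistic(
            small_cohort.participants, ModelSpec(fixed=(), group=SPEC.group)
        )
        chi2, df, p = likelihood_ratio_test(full, null)
        assert df == 6
        assert chi2 > 0 and p < 0.05

    def test_statistic_grows_roughly_linearly_with_sample_size(self):
        chi2s = []
        for n in (500, 1000, 2000):
            cohort = generate_cohort(CohortConfig(n_participants=n, seed=9))
            full = fit_multilevel_logistic(cohort.participants, SPEC)
            null = fit_multilevel_logistic(
                cohort.participants, ModelSpec(fixed=(), group=SPEC.group)
            )
            chi2s.append(likelihood_ratio_test(full, null)[0])
        assert chi2s[0] < chi2s[1] < chi2s[2]

    def test_non_nested_specs_rejected(self, small_cohort):
        full = fit_multilevel_logistic(small_cohort.participants, SPEC)
        other = fit_multilevel_logistic(
            small_cohort.participants,
            ModelSpec(fixed=("age", "gad7_total"), group=SPEC.group),
        )
        with pytest.raises(ValidationError, match="nest"):
            likelihood_ratio_test(full, other)


class TestWaldConventions:
    def test_reference_auc_row(self):
        fit = make_fit(0.53, 0.15)
        assert float(np.round(fit.or_[0], 2)) == 1.70
        assert np.round(fit.ci95[0], 2).tolist() == [1.27, 2.28]
        assert 3.53 <= fit.z[0] <= 3.56
        assert fit.p[0] < 0.001

    def test_reference_essential_worker_row(self):
        fit = make_fit(0.58, 0.10)
        assert float(np.round(fit.or_[0], 2)) == 1.79

    def test_null_coefficient(self):
        fit = make_fit(0.0, 0.2)
        assert fit.or_[0] == 1.0
        lo, hi = fit.ci95[0]
        assert lo * hi == pytest.approx(1.0, rel=1e-12)  # symmetric on the log scale

    def test_summary_table_columns(self, small_cohort):
        fit = fit_multilevel_logistic(small_cohort.participants, SPEC)
        table = wald_summary(fit)
        assert list(table["term"]) == ["intercept", *SPEC.fixed]
        assert np.allclose(table["or"], np.exp(table["estimate"]))
        assert (table["ci_low"] < table["or"]).all() and (table["or"] < table["ci_high"]).all()


def test_wald_interval_coverage_for_auc_effect():
    """~95% of 95% CIs for the AuC coefficient cover the generating value."""
    covered = 0
    n_rep = 200
    for seed in range(n_rep):
        cohort = generate_cohort(CohortConfig(n_participants=2000, seed=1000 + seed))
        fit = fit_multilevel_logistic(cohort.participants, SPEC)
        j = fit.names.index("auc")
        lo = fit.beta[j] - 1.96 * fit.se[j]
        hi = fit.beta[j] + 1.96 * fit.se[j]
        covered += lo <= 0.53 <= hi
    assert covered / n_rep == pytest.approx(0.95, abs=0.04)
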