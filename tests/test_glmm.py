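"""Poisson mixed-model inference: recovery, identities, checks, sensitivity."""

import numpy as np
import pytest

from imtrial import (
    DiagnosticError,
    GeneratorConfig,
    ModelData,
    Priors,
    build_model_data,
    detect_outliers,
    fit_poisson_glmm,
    posterior_predictive_check,
    sensitivity_suite,
    summarize_posterior,
)
from tests.conftest import make_randomised_dataset


@pytest.fixture(scope="module")
def effect_fit():
    rng = np.random.default_rng(77)
    ds = make_randomised_dataset(75, GeneratorConfig(), rng, n_immediate=36)
    data = build_model_data(ds)
    fit = fit_poisson_glmm(data, rng=np.random.default_rng(0), method="mcmc")
    return data, fit


def test_single_arm_rejected(rng):
    ds = make_randomised_dataset(10, GeneratorConfig(), rng, n_immediate=10)
    with pytest.raises(ValueError, match="both arms"):
        build_model_data(ds)


def test_unimputed_missing_rejected(rng):
    from imtrial import inject_missingness

    ds = make_randomised_dataset(10, GeneratorConfig(), rng)
    ds = inject_missingness(ds, 0.5, rng)
    with pytest.raises(ValueError, match="unimputed|imputation"):
        build_model_data(ds)


def test_mcmc_diagnostics_pass_and_recovery(effect_fit):
    data, fit = effect_fit
    assert fit.ok
    assert all(r <= 1.01 for r in fit.diagnostics["rhat"].values())
    s = summarize_posterior(fit)
    assert -2.4 < s.beta_treat_mean < -1.4     # true effect -1.9
    assert s.beta_treat_ci[0] < s.beta_treat_mean < s.beta_treat_ci[1]


def test_rate_ratio_is_exact_exponential(effect_fit):
    _, fit = effect_fit
    s = summarize_posterior(fit)
    assert s.rate_ratio == np.exp(s.beta_treat_mean)   # bit-level identity


def test_seed_determinism(effect_fit):
    data, fit = effect_fit
    again = fit_poisson_glmm(data, rng=np.random.default_rng(0), method="mcmc")
    np.testing.assert_array_equal(fit.flat("beta_treat"), again.flat("beta_treat"))


def test_laplace_close_to_mcmc(effect_fit):
    data, fit = effect_fit
    lap = fit_poisson_glmm(data, rng=np.random.default_rng(1), method="laplace")
    m_mc, _ = fit.beta_treat_normal_approx()
    m_lap, s_lap = lap.beta_treat_normal_approx()
    assert abs(m_mc - m_lap) < 3 * s_lap


def test_agrees_with_fixed_effects_glm_when_no_heterogeneity(rng):
    """sigma_u -> 0 data + near-flat priors: posterior mean matches the
    fixed-effects Poisson regression MLE (statsmodels oracle)."""
    import statsmodels.api as sm

    ds = make_randomised_dataset(
        60, GeneratorConfig(sigma_u=0.0, beta_treat=-1.0), rng
    )
    data = build_model_data(ds)
    flat = Priors(beta0_scale=20, beta_base_scale=20, beta_treat_scale=20,
                  sigma_u_scale=0.02)
    fit = fit_poisson_glmm(data, priors=flat, rng=np.random.default_rng(3), method="mcmc")
    exog = sm.add_constant(np.column_stack([data.x, data.treat]))
    glm = sm.GLM(data.totals, exog, family=sm.families.Poisson(),
                 exposure=np.full(data.n, 7.0)).fit()
    post_mean = fit.flat("beta_treat").mean()
    se = glm.bse[2]
    assert abs(post_mean - glm.params[2]) < max(0.5 * se, 0.05)


def test_arm_label_swap_negates_effect(rng):
    ds = make_randomised_dataset(60, GeneratorConfig(), rng)
    data = build_model_data(ds)
    swapped = ModelData(
        totals=data.totals, baseline_totals=data.baseline_totals,
        treat=1 - data.treat, day_counts=data.day_counts,
        participant_ids=data.participant_ids,
    )
    a = fit_poisson_glmm(data, rng=np.random.default_rng(5), method="laplace")
    b = fit_poisson_glmm(swapped, rng=np.random.default_rng(5), method="laplace")
    assert a.map_estimate["beta_treat"] == pytest.approx(
        -b.map_estimate["beta_treat"], abs=0.02
    )


class TestPosteriorPredictive:
    def test_self_consistent_data_gives_moderate_pvalues(self, effect_fit):
        data, fit = effect_fit
        pvals = posterior_predictive_check(fit, n_rep=400, rng=np.random.default_rng(9))
        assert all(0.01 < p < 0.99 for p in pvals.values()), pvals

    def test_variance_misfit_detected_when_heterogeneity_suppressed(self, rng):
        """Overdispersed counts fitted with sigma_u forced ~0: extreme variance p."""
        ds = make_randomised_dataset(160, GeneratorConfig(sigma_u=1.0), rng)
        data = build_model_data(ds)
        no_u = Priors(sigma_u_scale=1e-3)
        fit = fit_poisson_glmm(data, priors=no_u, rng=np.random.default_rng(4),
                               method="mcmc")
        pvals = posterior_predictive_check(fit, n_rep=400, rng=np.random.default_rng(10))
        var_ps = [pvals["immediate_var"], pvals["delayed_var"]]
        assert min(var_ps) < 0.01 or max(var_ps) > 0.99


class TestOutliers:
    def test_planted_outlier_flagged(self, rng):
        ds = make_randomised_dataset(40, GeneratorConfig(), rng)
        data = build_model_data(ds)
        inflated = data.totals.copy()
        victim = 5
        inflated[victim] = max(10 * inflated[victim], 80)
        data2 = ModelData(
            totals=inflated, baseline_totals=data.baseline_totals,
            treat=data.treat, day_counts=data.day_counts,
            participant_ids=data.participant_ids,
        )
        fit = fit_poisson_glmm(data2, rng=np.random.default_rng(6), method="laplace")
        report = detect_outliers(fit, data2)
        assert data.participant_ids[victim] in report.flagged

    def test_infinite_thresholds_flag_nothing(self, rng):
        ds = make_randomised_dataset(30, GeneratorConfig(), rng)
        data = build_model_data(ds)
        fit = fit_poisson_glmm(data, rng=np.random.default_rng(7), method="laplace")
        report = detect_outliers(fit, data, resid_threshold=np.inf,
                                 cooks_multiple=np.inf, leverage_multiple=np.inf)
        assert report.flagged == []

    def test_clean_data_low_flag_rate(self):
        flags = total = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            ds = make_randomised_dataset(40, GeneratorConfig(), rng)
            data = build_model_data(ds)
            fit = fit_poisson_glmm(data, rng=rng, method="laplace")
            flags += len(detect_outliers(fit, data).flagged)
            total += data.n
        assert flags / total <= 0.05


class TestSensitivity:
    def test_same_seed_identical(self, effect_fit):
        data, _ = effect_fit
        variants = [{"name": "default"}, {"name": "wide", "priors": Priors(beta_treat_scale=5.0)}]
        t1 = sensitivity_suite(data, variants, np.random.default_rng(8), method="laplace")
        t2 = sensitivity_suite(data, variants, np.random.default_rng(8), method="laplace")
        assert t1.equals(t2)

    def test_prior_scale_doubling_shifts_little(self, effect_fit):
        """Likelihood-dominated at n=75: doubling the effect prior scale moves
        the posterior mean by < 0.3."""
        data, _ = effect_fit
        variants = [
            {"name": "default", "priors": Priors()},
            {"name": "doubled", "priors": Priors(beta_treat_scale=5.0)},
        ]
        table = sensitivity_suite(data, variants, np.random.default_rng(13), method="mcmc")
        assert (table["status"] == "ok").all()
        assert table.attrs["max_pairwise_diff"] < 0.3

    def test_negbin_variant_and_outlier_subset(self, effect_fit):
        data, fit = effect_fit
        keep = np.ones(data.n, dtype=bool)
        report = detect_outliers(fit, data)
        for pid in report.flagged:
            keep[data.participant_ids.index(pid)] = False
        variants = [
            {"name": "poisson", "method": "mcmc"},
            {"name": "negbin", "family": "negbin", "method": "mcmc"},
            {"name": "no_outliers", "subset": keep, "method": "mcmc"},
        ]
        table = sensitivity_suite(data, variants, np.random.default_rng(14))
        ok = table[table["status"] == "ok"]
        assert len(ok) >= 2
        # same direction of effect everywhere, overlapping credible intervals
        assert (ok["beta_treat_mean"] < 0).all()
        assert ok["ci_low"].max() < ok["ci_high"].min()

    def test_failed_variant_recorded_not_raised(self, effect_fit):
        data, _ = effect_fit
        variants = [{"name": "bad_subset", "subset": data.treat == 1}]
        table = sensitivity_suite(data, variants, np.random.default_rng(15),
                                  method="laplace")
        assert table.iloc[0]["status"].startswith("failed")


def test_diagnostic_failure_refuses_summary(effect_fit):
    data, fit = effect_fit
    broken = fit_poisson_glmm(data, rng=np.random.default_rng(16), method="laplace")
    broken.diagnostics["rhat"]["beta_treat"] = 1.5
    with pytest.raises(DiagnosticError):
        summarize_posterior(broken)
    s = summarize_posterior(broken, force=True)
    assert np.isfinite(s.beta_treat_mean)
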