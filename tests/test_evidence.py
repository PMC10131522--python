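"""Directional Bayes factors and the sequential stopping logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import norm

from imtrial import (
    DesignConfig,
    GeneratorConfig,
    bf_directional,
    build_model_data,
    fit_poisson_glmm,
    savage_dickey_onesided,
    sequential_monitor,
    simulate_completer_stream,
)
from tests.conftest import make_randomised_dataset


def quadrature_onesided_bf(ybar, n, sigma, prior_sd=1.0):
    """Brute-force oracle for the conjugate normal-normal toy.

    One observation mean ybar with known SD sigma/sqrt(n); H+: theta < 0 with
    the prior truncated to the negative half-line; H0: theta = 0.  The Bayes
    factor is the ratio of marginal likelihoods by direct numerical
    integration.
    """
    se = sigma / np.sqrt(n)

    def integrand(theta):
        return norm.pdf(ybar, theta, se) * norm.pdf(theta, 0, prior_sd)

    num, _ = integrate.quad(integrand, -np.inf, 0.0, limit=200)
    num /= norm.cdf(0.0, 0.0, prior_sd)          # truncated-prior normalisation
    den = norm.pdf(ybar, 0.0, se)
    return num / den


def analytic_posterior(ybar, n, sigma, prior_sd=1.0):
    """Conjugate posterior N(m, v) for the toy problem."""
    se2 = sigma**2 / n
    v = 1.0 / (1.0 / prior_sd**2 + 1.0 / se2)
    m = v * ybar / se2
    return m, np.sqrt(v)


class TestSavageDickey:
    @pytest.mark.parametrize("ybar", np.linspace(-2.0, 2.0, 9))
    def test_matches_quadrature_oracle(self, ybar):
        """One-sided Savage-Dickey equals the marginal-likelihood ratio."""
        n, sigma = 12, 2.0
        m, s = analytic_posterior(ybar, n, sigma)
        bf = savage_dickey_onesided(
            post_density0=norm.pdf(0.0, m, s),
            post_mass_dir=norm.cdf(0.0, m, s),
            prior_loc=0.0, prior_scale=1.0, direction="positive_effect",
        )
        oracle = quadrature_onesided_bf(ybar, n, sigma)
        assert bf == pytest.approx(oracle, rel=0.05)

    def test_reciprocal_identity(self):
        m, s = analytic_posterior(0.7, 10, 2.0)
        bf = savage_dickey_onesided(norm.pdf(0, m, s), norm.cdf(0, m, s),
                                    0.0, 1.0, "positive_effect")
        assert bf * (1.0 / bf) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            savage_dickey_onesided(0.1, 0.5, 0.0, 1.0, "sideways")

    @settings(derandomize=True, max_examples=200)
    @given(
        m=st.floats(-4, 4), s=st.floats(0.05, 3),
        prior_scale=st.floats(0.3, 5),
    )
    def test_directional_bfs_partition_the_two_sided_bf(self, m, s, prior_scale):
        """Mixing the two one-sided BFs by their prior masses recovers the
        two-sided Savage-Dickey ratio prior(0)/posterior(0)."""
        from hypothesis import assume

        post0 = norm.pdf(0, m, s)
        assume(post0 > 1e-12)   # density at 0 representable
        mass_pos = norm.cdf(0, m, s)
        bf_pos = savage_dickey_onesided(post0, mass_pos, 0.0, prior_scale,
                                        "positive_effect")
        bf_neg = savage_dickey_onesided(post0, 1 - mass_pos, 0.0, prior_scale,
                                        "negative_effect")
        two_sided = norm.pdf(0, 0, prior_scale) / post0
        mixed = 0.5 * bf_pos + 0.5 * bf_neg   # symmetric prior: equal half-masses
        assert mixed == pytest.approx(two_sided, rel=1e-9)


@pytest.fixture(scope="module")
def weak_fit():
    rng = np.random.default_rng(55)
    ds = make_randomised_dataset(24, GeneratorConfig(beta_treat=-0.5), rng)
    data = build_model_data(ds)
    return fit_poisson_glmm(data, rng=np.random.default_rng(1), method="mcmc")


class TestBfDirectional:
    def test_directions_are_complementary_evidence(self, weak_fit):
        pos = bf_directional(weak_fit, "positive_effect")
        neg = bf_directional(weak_fit, "negative_effect")
        assert pos.bf > 0 and neg.bf > 0
        assert pos.bf * pos.reciprocal == pytest.approx(1.0, abs=1e-12)
        assert neg.bf * neg.reciprocal == pytest.approx(1.0, abs=1e-12)

    def test_kde_and_normal_density_paths_agree_roughly(self, weak_fit):
        a = bf_directional(weak_fit, "positive_effect", density="normal")
        b = bf_directional(weak_fit, "positive_effect", density="kde")
        assert np.log(a.bf) == pytest.approx(np.log(b.bf), abs=0.7)

    def test_bridge_cross_check(self):
        """Savage-Dickey (kde density) and bridge sampling agree within 25%
        relative error on small simulated datasets - both estimate the same
        marginal-likelihood ratio."""
        rel_errs = []
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            ds = make_randomised_dataset(20, GeneratorConfig(beta_treat=-0.3), rng)
            data = build_model_data(ds)
            fit = fit_poisson_glmm(data, rng=np.random.default_rng(seed),
                                   method="mcmc")
            sd = bf_directional(fit, "positive_effect", density="kde")
            br = bf_directional(fit, "positive_effect", method="bridge",
                                rng=np.random.default_rng(seed + 40))
            rel_errs.append(abs(br.bf - sd.bf) / br.bf)
        assert np.median(rel_errs) < 0.25
        assert max(rel_errs) < 0.6

    def test_refuses_failed_fit(self, weak_fit):
        import copy

        broken = copy.copy(weak_fit)
        broken.diagnostics = dict(weak_fit.diagnostics)
        broken.diagnostics["rhat"] = {"beta_treat": 2.0}
        with pytest.raises(RuntimeError):
            bf_directional(broken, "positive_effect")


class TestSequentialMonitor:
    def test_infinite_threshold_runs_to_ceiling(self, rng):
        design = DesignConfig(bf_threshold=np.inf, n_max=32, first_look=20, look_step=4)
        gen = GeneratorConfig(beta_treat=0.0)
        ds = simulate_completer_stream(gen, design, 32, rng)
        trace = sequential_monitor(ds, design, np.random.default_rng(2))
        assert trace.decision == "max_reached"
        assert not trace.stopped_early
        assert [l.n for l in trace.looks] == [20, 24, 28, 32]

    def test_explicit_look_schedule_reproduced(self, rng):
        """The study's seven analysis points drive the trace when configured."""
        schedule = [20, 23, 29, 37, 41, 45, 75]
        design = DesignConfig(looks=schedule, n_max=75, bf_threshold=np.inf)
        ds = simulate_completer_stream(GeneratorConfig(beta_treat=0.0), design, 75, rng)
        trace = sequential_monitor(ds, design, np.random.default_rng(3))
        assert [l.n for l in trace.looks] == schedule
        assert trace.decision == "max_reached"

    def test_harm_check_gates_efficacy_check(self, rng):
        """A strong *harmful* effect stops via the negative-effect gate, and
        the efficacy BF is never computed at that look."""
        design = DesignConfig(n_max=40)
        gen = GeneratorConfig(beta_treat=+1.2)   # intervention increases IMs
        ds = simulate_completer_stream(gen, design, 40, rng)
        trace = sequential_monitor(ds, design, np.random.default_rng(4))
        assert trace.decision == "stop_negative"
        assert trace.looks[-1].bf_positive is None

    def test_strong_effect_stops_early(self, rng):
        design = DesignConfig()
        ds = simulate_completer_stream(GeneratorConfig(), design, 75, rng)
        trace = sequential_monitor(ds, design, np.random.default_rng(5))
        assert trace.decision == "stop_positive"
        assert trace.n_at_decision <= 40

    def test_short_stream_warns_inconclusive(self, rng):
        design = DesignConfig()
        ds = simulate_completer_stream(GeneratorConfig(), design, 10, rng)
        trace = sequential_monitor(ds, design, np.random.default_rng(6))
        assert trace.decision == "inconclusive"
        assert trace.warning is not None

    def test_log_bf_grows_with_information(self, rng):
        """Median efficacy log-BF over replicate fixed-n datasets is
        non-decreasing in n under a true positive effect."""
        design = DesignConfig()
        medians = []
        for n in (12, 24, 48):
            bfs = []
            for rep in range(20):
                sub = np.random.default_rng(700 + 13 * rep + n)
                ds = simulate_completer_stream(GeneratorConfig(), design, n, sub)
                data = build_model_data(ds)
                fit = fit_poisson_glmm(data, rng=sub, method="laplace")
                bfs.append(np.log(bf_directional(fit, "positive_effect").bf))
            medians.append(np.median(bfs))
        assert medians[0] <= medians[1] <= medians[2]
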