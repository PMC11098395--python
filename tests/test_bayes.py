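"""Metropolis-Hastings sampler, loss-based estimates, credible intervals."""

import numpy as np
import pytest

from ledcens import (CaseQuantities, LEDParams, LossSpec, MCMCConfig,
                     PosteriorDraws, PriorSpec, bayes_point_estimates,
                     credible_interval, led_hrf, led_rng, led_sf,
                     log_likelihood, log_posterior, make_scheme_I, run_mh,
                     simulate_iatii)


def make_draws(chain, Q=0, t_eval=0.25):
    chain = np.asarray(chain, dtype=float)
    return PosteriorDraws(nu=chain, eta=chain.copy(), S=chain.copy(),
                          h=chain.copy(), Q=Q, t_eval=t_eval)


class TestLogPosterior:
    def test_flat_prior_limit_differs_by_constant(self, sample_C, rng):
        """a = 1, b -> 0 leaves only the likelihood up to a constant."""
        prior = PriorSpec(1.0, 1e-12, 1.0, 1e-12)
        p0 = (0.4, 1.3)
        offset = log_posterior(p0, sample_C, prior) - log_likelihood(p0, sample_C)
        for _ in range(20):
            p = np.exp(rng.uniform(-1, 1, 2))
            diff = log_posterior(p, sample_C, prior) - log_likelihood(p, sample_C)
            assert diff == pytest.approx(offset, abs=1e-9)

    def test_gradient_against_finite_differences(self, sample_B, rng):
        prior = PriorSpec(2.0, 1.5, 3.0, 2.0)
        h = 1e-6
        for _ in range(100):
            nu, eta = np.exp(rng.uniform(-1, 1, 2))
            g_nu = (log_posterior((nu + h, eta), sample_B, prior)
                    - log_posterior((nu - h, eta), sample_B, prior)) / (2 * h)
            from ledcens import score
            g = score((nu, eta), sample_B)
            g_expected = g[0] + (prior.a1 - 1) / nu - prior.b1
            assert g_nu == pytest.approx(g_expected, rel=1e-5, abs=1e-5)

    def test_prior_mode(self):
        """With the likelihood absent the posterior mode is the gamma mode."""
        prior = PriorSpec(3.0, 2.0, 4.0, 5.0)
        lp = lambda nu, eta: ((prior.a1 - 1) * np.log(nu) - prior.b1 * nu  # noqa: E731
                              + (prior.a2 - 1) * np.log(eta) - prior.b2 * eta)
        nus = np.linspace(0.05, 5, 800)
        assert nus[np.argmax([lp(v, 1.0) for v in nus])] == pytest.approx(
            (prior.a1 - 1) / prior.b1, abs=0.01)
        etas = np.linspace(0.05, 5, 800)
        assert etas[np.argmax([lp(1.0, v) for v in etas])] == pytest.approx(
            (prior.a2 - 1) / prior.b2, abs=0.01)


class TestSampler:
    def test_reproducible_given_seed(self, sample_C):
        cfg = MCMCConfig(P=400, Q=100, seed=5, t_eval=0.5)
        d1 = run_mh(sample_C, PriorSpec.diffuse(), cfg)
        d2 = run_mh(sample_C, PriorSpec.diffuse(), cfg)
        np.testing.assert_array_equal(d1.nu, d2.nu)
        np.testing.assert_array_equal(d1.h, d2.h)

    def test_tiny_proposals_always_accepted(self, sample_C):
        cfg = MCMCConfig(P=300, Q=0, seed=1, proposal_sd=(1e-12, 1e-12))
        d = run_mh(sample_C, PriorSpec.diffuse(), cfg)
        assert min(d.accept_rate) > 0.999
        assert np.ptp(d.nu) < 1e-9  # chain barely moves

    def test_reliability_chains_are_exact_transforms(self, sample_B):
        cfg = MCMCConfig(P=500, Q=100, seed=3, t_eval=0.6)
        d = run_mh(sample_B, PriorSpec.diffuse(), cfg)
        S = np.array([led_sf(0.6, (a, b)) for a, b in zip(d.nu, d.eta)])
        h = np.array([led_hrf(0.6, (a, b)) for a, b in zip(d.nu, d.eta)])
        np.testing.assert_allclose(d.S, S, rtol=1e-12)
        np.testing.assert_allclose(d.h, h, rtol=1e-12)
        assert np.all(d.nu > 0) and np.all(d.eta > 0)

    def test_posterior_mean_matches_quadrature_oracle(self):
        """2-D dense-grid quadrature on a tiny complete sample."""
        data = np.sort(led_rng(6, LEDParams(1.5, 1.2), seed=17))
        q = CaseQuantities.from_complete(data)
        prior = PriorSpec(2.0, 2.0, 2.0, 2.0)
        nus = np.linspace(0.01, 6.0, 220)
        etas = np.linspace(0.01, 6.0, 220)
        logpost = np.array([[log_posterior((a, b), q, prior) for a in nus]
                            for b in etas])
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_nu = float((w.sum(axis=0) * nus).sum())
        mean_eta = float((w.sum(axis=1) * etas).sum())
        cfg = MCMCConfig(P=12_000, Q=2_000, seed=8)
        d = run_mh(q, prior, cfg)
        # 2 x a conservative MC standard error from the autocorrelated chain
        for chain, target in ((d.post_burn("nu"), mean_nu),
                              (d.post_burn("eta"), mean_eta)):
            blocks = chain[:10_000].reshape(50, 200).mean(axis=1)
            mcse = blocks.std(ddof=1) / np.sqrt(len(blocks))
            assert abs(chain.mean() - target) < max(3 * mcse, 0.02)

    def test_bernstein_von_mises_with_diffuse_prior(self):
        """Large-sample posterior centres near the MLE."""
        from ledcens import fit_mle
        scheme = make_scheme_I(200, 200, 1e8, 1e9)
        sample = simulate_iatii(LEDParams(1.5, 1.2), scheme, seed=44)
        fit = fit_mle(sample)
        d = run_mh(sample, PriorSpec.diffuse(),
                   MCMCConfig(P=4_000, Q=1_000, seed=2), fit=fit)
        for name, est in (("nu", fit.estimates.nu), ("eta", fit.estimates.eta)):
            chain = d.post_burn(name)
            assert abs(chain.mean() - est) < 2 * chain.std()


class TestLossEstimates:
    def test_linex_limit_recovers_posterior_mean(self, sample_C):
        d = run_mh(sample_C, PriorSpec.diffuse(), MCMCConfig(P=1_500, Q=300, seed=9))
        self_est = bayes_point_estimates(d, LossSpec("SELF"))
        linex_est = bayes_point_estimates(d, LossSpec("LINEX", 1e-6))
        for q in ("nu", "eta", "S", "h"):
            assert linex_est[q] == pytest.approx(self_est[q], abs=1e-4)

    def test_constant_chain_returns_constant(self):
        d = make_draws(np.full(500, 3.25))
        with pytest.warns(UserWarning):
            assert bayes_point_estimates(d, LossSpec("SELF"))["nu"] == 3.25
        with pytest.warns(UserWarning):
            assert bayes_point_estimates(d, LossSpec("LINEX", 0.7))["nu"] == 3.25

    def test_linex_below_self_for_positive_p(self, rng):
        """Jensen direction: -(1/p) log E e^{-p X} < E X for p > 0."""
        d = make_draws(rng.gamma(3.0, 0.5, size=4_000))
        self_est = bayes_point_estimates(d, LossSpec("SELF"))["nu"]
        linex_est = bayes_point_estimates(d, LossSpec("LINEX", 0.5))["nu"]
        assert linex_est < self_est

    def test_linex_formula_against_direct_evaluation(self, rng):
        chain = rng.uniform(0.5, 2.0, size=2_000)
        d = make_draws(chain)
        p = 0.5
        direct = -np.log(np.mean(np.exp(-p * chain))) / p
        assert bayes_point_estimates(d, LossSpec("LINEX", p))["nu"] == \
            pytest.approx(direct, rel=1e-12)

    def test_loss_spec_validation(self):
        with pytest.raises(ValueError):
            LossSpec("LINEX", 0.0)
        with pytest.raises(ValueError):
            LossSpec("quadratic")


class TestCredibleIntervals:
    def test_uniform_chain_percentile_interval(self, rng):
        d = make_draws(rng.random(40_000))
        ci = credible_interval(d, 0.95, "percentile")["nu"]
        assert ci.lower == pytest.approx(0.025, abs=0.01)
        assert ci.upper == pytest.approx(0.975, abs=0.01)

    def test_methods_agree_on_symmetric_chain(self, rng):
        d = make_draws(rng.normal(5.0, 1.0, size=30_000))
        pct = credible_interval(d, 0.95, "percentile")["nu"]
        sht = credible_interval(d, 0.95, "shortest")["nu"]
        assert sht.width <= pct.width + 1e-12
        assert pct.lower == pytest.approx(sht.lower, abs=0.15)
        med = 5.0
        assert pct.contains(med) and sht.contains(med)

    def test_level_validation(self, rng):
        d = make_draws(rng.random(1_000))
        with pytest.raises(ValueError):
            credible_interval(d, 1.2)
        with pytest.raises(ValueError):
            credible_interval(d, 0.95, "hpd-exact")
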