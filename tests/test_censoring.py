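"""Censoring designs, case classification and the IAT-II PCS simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ledcens import (CensoringScheme, LEDParams, censor_complete_data,
                     classify_sample, complete_scheme, format_removals,
                     make_scheme_I, make_scheme_II, make_scheme_III,
                     parse_removals, simulate_iatii)

TRUTH = LEDParams(1.5, 1.2)


class TestSchemes:
    def test_standard_schemes(self):
        s1 = make_scheme_I(40, 20, 0.4, 0.8)
        assert s1.R == (20,) + (0,) * 19
        s2 = make_scheme_II(40, 20, 0.4, 0.8)
        assert s2.R == (0,) * 19 + (20,)
        s3 = make_scheme_III(40, 20, 0.4, 0.8)
        assert s3.R[9] == 20 and sum(s3.R) == 20
        for s in (s1, s2, s3):
            assert sum(s.R) == s.n - s.m

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            make_scheme_III(40, 19, 0.4, 0.8)  # odd m
        with pytest.raises(ValueError):
            CensoringScheme(10, 5, (1, 1, 1, 1, 1), 0.5, 0.4)  # T2 < T1
        with pytest.raises(ValueError):
            CensoringScheme(10, 5, (9, 0, 0, 0, 0), 0.4, 0.8)  # sum(R) != n-m
        with pytest.raises(ValueError):
            CensoringScheme(10, 5, (-1, 6, 0, 0, 0), 0.4, 0.8)

    def test_removal_shorthand(self):
        assert parse_removals("4*2, 0*10, 4*2") == (4,) * 2 + (0,) * 10 + (4,) * 2
        assert parse_removals("3,0,1") == (3, 0, 1)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 9), min_size=1, max_size=30))
    def test_shorthand_roundtrip(self, R):
        assert parse_removals(format_removals(R)) == tuple(R)

    def test_dict_roundtrip(self):
        s = make_scheme_I(30, 14, 1.0, 2.0)
        assert CensoringScheme.from_dict(s.to_dict()) == s


class TestClassify:
    def test_packaged_censored_samples(self, sample_A, sample_B, sample_C):
        """Case labels and Table-1 quantities of the packaged samples."""
        assert (sample_A.case, sample_A.E1, sample_A.E2, sample_A.B,
                sample_A.Tstar) == ("III", 8, 13, 9, 2.25)
        assert (sample_B.case, sample_B.E1, sample_B.E2, sample_B.B,
                sample_B.Tstar) == ("II", 8, 14, 12, 2.46)
        assert (sample_C.case, sample_C.E1, sample_C.E2, sample_C.B,
                sample_C.Tstar) == ("III", 6, 12, 10, 2.0)

    def test_accounting_identity_of_fixtures(self, sample_A, sample_B, sample_C):
        for s in (sample_A, sample_B, sample_C):
            assert s.E2 + s.applied_removals.sum() + s.B == s.scheme.n

    def test_invalid_inputs(self):
        scheme = make_scheme_I(10, 5, 0.5, 1.0)
        with pytest.raises(ValueError):
            classify_sample([0.3, 0.2, 0.4], scheme)       # unsorted
        with pytest.raises(ValueError):
            classify_sample([0.1] * 6, scheme)             # more than m
        with pytest.raises(ValueError):
            classify_sample([-0.1, 0.2], scheme)           # negative times


class TestSimulator:
    def test_accounting_holds_on_every_draw(self):
        schemes = [make_scheme_I(20, 10, 0.4, 0.8),
                   make_scheme_II(20, 10, 0.4, 0.8),
                   make_scheme_III(20, 10, 0.4, 0.8)]
        for k in range(600):
            s = simulate_iatii(TRUTH, schemes[k % 3], seed=k)
            assert s.E2 + s.applied_removals.sum() + s.B == s.scheme.n

    def test_classification_roundtrip(self):
        scheme = make_scheme_I(25, 12, 0.4, 0.9)
        for k in range(300):
            s = simulate_iatii(TRUTH, scheme, seed=1000 + k)
            c = classify_sample(s.x, scheme)
            assert (c.case, c.E1, c.E2, c.B, c.Tstar) == \
                   (s.case, s.E1, s.E2, s.B, s.Tstar)
            np.testing.assert_array_equal(c.applied_removals, s.applied_removals)

    def test_threshold_limits_control_cases(self):
        huge = make_scheme_I(15, 8, 1e8, 1e9)
        cases = {simulate_iatii(TRUTH, huge, seed=k).case for k in range(200)}
        assert cases == {"I"}  # T1 huge: neither adaptation nor hard stop
        no_stop = make_scheme_I(15, 8, 0.3, 1e9)
        cases = {simulate_iatii(TRUTH, no_stop, seed=k).case for k in range(200)}
        assert "III" not in cases

    def test_all_three_cases_reachable(self):
        scheme = make_scheme_I(40, 20, 0.4, 0.8)
        cases = [simulate_iatii(TRUTH, scheme, seed=k).case for k in range(400)]
        frac = {c: cases.count(c) / len(cases) for c in "I II III".split()}
        assert 0 < frac["III"] < 1  # mixture, not a point mass

    def test_first_failure_is_minimum_of_exponentials(self):
        """With eta = 1 and n = 5 on test, X_(1) ~ Exp(5 nu)."""
        p = LEDParams(2.0, 1.0)
        scheme = CensoringScheme(5, 5, (0,) * 5, 1e8, 1e9)
        firsts = np.array([simulate_iatii(p, scheme, seed=k).x[0]
                           for k in range(4000)])
        res = stats.kstest(firsts, stats.expon(scale=1 / (5 * 2.0)).cdf)
        assert res.pvalue > 0.01

    def test_complete_design_reproduces_iid_sampling(self):
        """m = n, R = 0, huge thresholds: sorted i.i.d. sample."""
        scheme = complete_scheme(8)
        first = [simulate_iatii(TRUTH, scheme, seed=k).x[0] for k in range(3000)]
        # the first order statistic of n iid draws has sf S(x)^n
        from ledcens import led_sf
        cdf = lambda x: 1.0 - led_sf(x, TRUTH) ** 8  # noqa: E731
        assert stats.kstest(np.array(first), cdf).pvalue > 0.01

    def test_sequential_sampler_matches_literal_latent_oracle(self):
        """Brute-force oracle: run the withdrawal/stopping rules on n i.i.d.
        latent lifetimes and compare the joint law of (case, E1, E2)."""
        scheme = CensoringScheme(5, 3, (1, 0, 1), 0.35, 0.75)
        reps = 20_000
        rng = np.random.default_rng(99)

        def latent_run(rng):
            from ledcens import led_quantile
            pool = list(np.sort(led_quantile(rng.random(5), TRUTH)))
            x = []
            i = 0
            while i < scheme.m and pool:
                xi = pool.pop(0)
                if xi >= scheme.T2:
                    break
                x.append(xi)
                if xi < scheme.T1 and scheme.R[i] > 0:
                    k = min(scheme.R[i], len(pool))
                    for idx in sorted(rng.choice(len(pool), k, replace=False),
                                      reverse=True):
                        pool.pop(int(idx))
                i += 1
            s = classify_sample(np.asarray(x), scheme)
            return s.case, s.E1, s.E2

        keys = {}
        counts_latent = {}
        counts_seq = {}
        for k in range(reps):
            key = latent_run(rng)
            counts_latent[key] = counts_latent.get(key, 0) + 1
            s = simulate_iatii(TRUTH, scheme, seed=rng)
            key2 = (s.case, s.E1, s.E2)
            counts_seq[key2] = counts_seq.get(key2, 0) + 1
        keys = sorted(set(counts_latent) | set(counts_seq))
        obs = np.array([[counts_latent.get(k, 0) for k in keys],
                        [counts_seq.get(k, 0) for k in keys]])
        # merge rare categories to keep expected counts healthy
        keep = obs.sum(axis=0) >= 10
        merged = np.column_stack([obs[:, keep], obs[:, ~keep].sum(axis=1)]) \
            if (~keep).any() else obs[:, keep]
        _, pvalue, *_ = stats.chi2_contingency(merged)
        assert pvalue > 0.001


class TestCensorCompleteData:
    def test_no_censoring_returns_data(self, rme):
        s = censor_complete_data(rme, complete_scheme(30), seed=0)
        np.testing.assert_array_equal(s.x, np.sort(rme))
        assert s.B == 0 and s.applied_removals.sum() == 0

    def test_output_is_subset_with_closed_accounting(self, rme, sample_A):
        s = censor_complete_data(rme, sample_A.scheme, seed=5)
        assert set(np.round(s.x, 10)) <= set(np.round(rme, 10))
        assert s.E2 + s.applied_removals.sum() + s.B == 30
        assert s.case in ("I", "II", "III")

    def test_length_mismatch_rejected(self, rme):
        with pytest.raises(ValueError):
            censor_complete_data(rme[:-1], complete_scheme(30), seed=0)
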