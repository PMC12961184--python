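"""The follow-up tests: alpha_n comparator, asymptotic Grenander test,
smoothed Grenander test with smoothed bootstrap, and the cutoff tool."""

import numpy as np
import pytest

import curefollowup as cf
from curefollowup.exceptions import InvalidInputError


@pytest.fixture(scope="module")
def level_config():
    spec = cf.make_setting(1, p=0.8, delta_g=0.2)
    return cf.TestConfig(
        tau=cf.uncured_quantile(spec, 0.9995),
        tau_g=cf.uncured_quantile(spec, 0.90),
        B=150, seed=404,
    )


@pytest.fixture(scope="module")
def level_sample(level_config):
    spec = cf.make_setting(1, p=0.8, delta_g=0.2)
    return cf.generate_sample(spec, level_config.tau_g, n=400, seed=2024)


class TestAlphaN:
    def test_hand_example(self, toy4):
        res = cf.alpha_n_test(toy4, cf.TestConfig(tau=10.0))
        # interval (2*3-4, 3] = (2, 3] holds one of four events
        assert res.statistic == pytest.approx(0.25)
        assert res.p_value == pytest.approx(0.75**4)
        assert not res.reject

    def test_largest_time_uncensored_gives_empty_interval(self):
        s = cf.SurvivalSample([1, 2, 3], [0, 1, 1])
        res = cf.alpha_n_test(s, cf.TestConfig(tau=10.0))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_brute_force_recount(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(1.0, 100).round(2)
        events = (rng.uniform(size=100) < 0.6).astype(int)
        s = cf.SurvivalSample(times, events)
        res = cf.alpha_n_test(s, cf.TestConfig(tau=times.max() + 5))
        y, yt = s.y_max, s.y_max_event
        count = sum(
            1 for t, d in zip(times, events)
            if d == 1 and 2 * yt - y < t <= yt
        )
        assert res.statistic == pytest.approx(count / 100)
        assert res.p_value == pytest.approx((1 - count / 100) ** 100)

    def test_no_events_rejected(self):
        s = cf.SurvivalSample([1, 2], [0, 0])
        with pytest.raises(InvalidInputError):
            cf.alpha_n_test(s, cf.TestConfig(tau=10.0))


class TestApplyCutoff:
    def test_rule_application(self):
        s = cf.SurvivalSample([80, 100, 171], [1, 0, 0])
        cut = cf.apply_cutoff(s, 90)
        np.testing.assert_array_equal(cut.times, [80, 90, 90])
        np.testing.assert_array_equal(cut.events, [1, 0, 0])

    def test_identity_beyond_max(self, toy4):
        cut = cf.apply_cutoff(toy4, 100)
        np.testing.assert_array_equal(cut.times, toy4.times)
        np.testing.assert_array_equal(cut.events, toy4.events)

    def test_idempotent(self, level_sample):
        once = cf.apply_cutoff(level_sample, 1.7)
        twice = cf.apply_cutoff(once, 1.7)
        np.testing.assert_array_equal(once.times, twice.times)
        np.testing.assert_array_equal(once.events, twice.events)


class TestGrenanderTest:
    def test_epsilon_zero_never_rejects(self, level_sample, level_config,
                                        slope_table):
        from dataclasses import replace
        cfg = replace(level_config, epsilon=0.0)
        res = cf.grenander_test(level_sample, cfg, slope_table)
        assert res.statistic > 0
        assert res.threshold < res.statistic
        assert not res.reject

    def test_decision_matches_p_value(self, level_sample, level_config,
                                      slope_table):
        res = cf.grenander_test(level_sample, level_config, slope_table)
        assert res.reject == (res.p_value < level_config.alpha)
        assert res.diagnostics["A1_hat"] > 0

    def test_diagnostics_carry_plugins(self, level_sample, level_config,
                                       slope_table):
        res = cf.grenander_test(level_sample, level_config, slope_table)
        d = res.diagnostics
        assert 0 < d["censoring_mass"] <= 1
        assert 0 < d["F_n_tau_g"] < 1
        assert d["evaluation_point"] == pytest.approx(
            d["tau_g"] * (1 - level_sample.n ** -level_config.a)
        )


class TestSmoothedBootstrap:
    def test_output_shape_and_reproducibility(self, level_sample, level_config):
        w1 = cf.smoothed_bootstrap(level_sample, level_config)
        w2 = cf.smoothed_bootstrap(level_sample, level_config)
        assert w1.shape == (level_config.B,)
        assert np.all(np.isfinite(w1))
        np.testing.assert_array_equal(w1, w2)

    def test_bootstrap_centres_near_oversmoothed_value(self, level_sample,
                                                       level_config):
        # the centred statistics n^{2/5}(f* - f~) should straddle zero
        w = cf.smoothed_bootstrap(level_sample, level_config)
        n = level_sample.n
        sd_fstar = np.std(w) * n ** -0.4
        assert abs(np.mean(w)) * n ** -0.4 < 3 * sd_fstar

    def test_no_events_is_degenerate(self, level_config):
        s = cf.SurvivalSample([1.0, 2.0, 3.0], [0, 0, 0])
        from dataclasses import replace
        cfg = replace(level_config, tau_g=3.0, tau=10.0)
        with pytest.raises(cf.DegenerateDensityError):
            cf.smoothed_bootstrap(s, cfg)


class TestSmoothedTest:
    def test_deterministic_given_seed(self, level_sample, level_config):
        r1 = cf.smoothed_test(level_sample, level_config)
        r2 = cf.smoothed_test(level_sample, level_config)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic
        assert r1.reject == r2.reject

    def test_decision_matches_p_value(self, level_sample, level_config):
        res = cf.smoothed_test(level_sample, level_config)
        assert res.reject == (res.p_value < level_config.alpha)

    def test_p_value_nonincreasing_in_epsilon(self, level_sample, level_config):
        from dataclasses import replace
        pvals = [
            cf.smoothed_test(
                level_sample, replace(level_config, epsilon=eps)
            ).p_value
            for eps in (0.0, 0.01, 0.05, 0.2)
        ]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_p_value_nondecreasing_in_tau(self, level_sample, level_config):
        # larger horizon tau shrinks the density bound: more conservative
        from dataclasses import replace
        pvals = [
            cf.smoothed_test(
                level_sample, replace(level_config, tau=tau)
            ).p_value
            for tau in (4.0, 6.0, 9.0, 15.0)
        ]
        assert all(a <= b for a, b in zip(pvals, pvals[1:]))

    def test_tau_not_beyond_tau_g_rejected(self, level_sample, level_config):
        from dataclasses import replace
        cfg = replace(level_config, tau=1.0)
        with pytest.raises(InvalidInputError):
            cf.smoothed_test(level_sample, cfg)

    def test_tau_g_estimated_by_largest_observation(self, level_sample,
                                                    level_config):
        from dataclasses import replace
        cfg = replace(level_config, tau_g=None)
        res = cf.smoothed_test(level_sample, cfg)
        assert res.diagnostics["tau_g"] == pytest.approx(level_sample.y_max)
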