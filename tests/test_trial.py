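from statistics import NormalDist

import numpy as np
import pytest

import enrichsurv as es

from conftest import exponential_curve, make_dataset


def events_oracle(alpha, power, hr):
    """Independent evaluation of the log-rank events formula (stdlib quantiles)."""
    z = NormalDist().inv_cdf(1 - alpha / 2) + NormalDist().inv_cdf(power)
    return 4 * z**2 / np.log(hr) ** 2


class TestEventsRequired:
    @pytest.mark.parametrize(
        "alpha,power,hr",
        [(0.05, 0.90, 0.8), (0.05, 0.80, 0.5), (0.01, 0.95, 0.7)],
    )
    def test_matches_independent_oracle(self, alpha, power, hr):
        got = es.events_required(es.TestingSpec(alpha, power, hr))
        assert got == pytest.approx(events_oracle(alpha, power, hr), rel=1e-6)

    def test_reference_values(self):
        assert es.events_required(es.TestingSpec(0.05, 0.90, 0.8)) == pytest.approx(
            844.1, abs=0.05
        )
        assert es.events_required(es.TestingSpec(0.05, 0.80, 0.5)) == pytest.approx(
            65.3, abs=0.05
        )

    def test_null_hazard_ratio_is_infeasible(self):
        with pytest.raises(es.InfeasibleDesignError):
            es.events_required(es.TestingSpec(0.05, 0.9, 1.0))


class TestEventRatesFixed:
    def test_no_events(self):
        r = es.event_rates_fixed(1.0, 0.0, 0.8)
        assert r.p_control == 0.0 and r.p_treatment == 0.0

    def test_power_relationship(self):
        r = es.event_rates_fixed(0.83, 0.0, 0.8)
        assert r.p_control == pytest.approx(0.17)
        assert r.p_treatment == pytest.approx(1 - 0.83**0.8)
        assert r.p_treatment == pytest.approx(0.1385, abs=5e-4)

    def test_delta_method_sd(self):
        r = es.event_rates_fixed(0.83, 0.01, 0.8)
        assert r.sd_p == pytest.approx((1 + 0.8 * 0.83**-0.2) * 0.01)
        assert r.sd_p == pytest.approx(0.0183, abs=5e-4)

    @pytest.mark.parametrize("s", [0.5, 0.8, 0.95])
    @pytest.mark.parametrize("hr", [0.5, 0.8])
    def test_delta_slope_matches_numeric_differentiation(self, s, hr):
        """|d(pC+pT)/dS| by central differences vs the closed-form slope."""
        h = 1e-6
        p = lambda ss: (1 - ss) + (1 - ss**hr)
        numeric = abs((p(s + h) - p(s - h)) / (2 * h))
        closed = 1 + hr * s ** (hr - 1)
        assert closed == pytest.approx(numeric, rel=1e-4)

    def test_treatment_rate_below_control_when_hr_lt_1(self):
        for s in np.linspace(0.05, 0.99, 20):
            r = es.event_rates_fixed(s, 0.0, 0.8)
            assert r.p_treatment <= r.p_control
        r = es.event_rates_fixed(0.7, 0.0, 1.0)
        assert r.p_treatment == pytest.approx(r.p_control)

    def test_zero_survival_flags_sd_unreliable(self):
        r = es.event_rates_fixed(0.0, 0.01, 0.8)
        assert r.p_control == 1.0
        assert np.isnan(r.sd_p)


class TestEventRatesAccrual:
    def test_no_events(self):
        d = make_dataset(np.full(30, 50.0), np.zeros(30, dtype=int))
        curve = es.kaplan_meier(d)
        r = es.event_rates_accrual(curve, 12.0, 36.0, 0.8)
        assert r.p_control == 0.0 and r.p_treatment == 0.0

    def test_simpson_on_exponential_survival(self):
        lam = -np.log(0.82) / 48
        curve = exponential_curve(lam, max_time=50.0, n_points=200_000)
        r = es.event_rates_accrual(curve, 12.0, 36.0, 0.8)
        s = np.exp(-lam * np.array([36.0, 42.0, 48.0]))
        expected = 1 - (s[0] + 4 * s[1] + s[2]) / 6
        assert r.p_control == pytest.approx(expected, abs=1e-4)
        assert r.p_control == pytest.approx(0.1593, abs=1e-4)
        # cross-check against the exact uniform-entry average (1/a) int F(f+u) du
        u = np.linspace(0, 12, 100_001)
        exact = np.trapezoid(1 - np.exp(-lam * (36 + u)), u) / 12
        assert r.p_control == pytest.approx(exact, abs=1e-4)

    def test_degenerate_accrual_reduces_to_fixed(self):
        curve = exponential_curve(0.005, max_time=50.0, n_points=50_000)
        r_acc = es.event_rates_accrual(curve, 1e-9, 36.0, 0.8)
        s36 = es.survival_at(curve, 36.0)[0]
        r_fix = es.event_rates_fixed(s36, 0.0, 0.8)
        assert r_acc.p_control == pytest.approx(r_fix.p_control, abs=1e-9)

    def test_rate_between_fixed_endpoints(self):
        curve = exponential_curve(0.01, max_time=50.0, n_points=50_000)
        r = es.event_rates_accrual(curve, 12.0, 36.0, 0.8)
        lo = 1 - es.survival_at(curve, 36.0)[0]
        hi = 1 - es.survival_at(curve, 48.0)[0]
        assert lo < r.p_control < hi

    def test_strict_mode_rejects_short_curve(self, hand_km_curve):
        with pytest.raises(es.ExtrapolationError):
            es.event_rates_accrual(hand_km_curve, 12.0, 36.0, 0.8)


class TestSampleSize:
    def test_everyone_events_gives_required_events(self):
        r = es.EventRateEstimate(1.0, 1.0, 0.0)
        assert es.sample_size(844.1, r).total_n == pytest.approx(844.1)

    def test_worked_example(self):
        r = es.EventRateEstimate(0.17, 0.1385, 0.0183)
        res = es.sample_size(844.1, r)
        assert res.total_n == pytest.approx(2 * 844.1 / 0.3085, rel=1e-12)
        assert res.total_n == pytest.approx(5472, abs=2)
        # solving N (pC + pT) / 2 = N0 back
        assert res.total_n * 0.3085 / 2 == pytest.approx(844.1)
        assert res.sd_n == pytest.approx(2 * 844.1 / 0.3085**2 * 0.0183, rel=1e-12)
        assert res.sd_n == pytest.approx(325, abs=1)

    def test_n_at_least_required_events_and_decreasing_in_rate(self):
        n0 = 500.0
        sizes = [
            es.sample_size(n0, es.EventRateEstimate(p, p * 0.9, 0.0)).total_n
            for p in np.linspace(0.05, 1.0, 30)
        ]
        assert np.all(np.diff(sizes) < 0)
        assert np.all(np.asarray(sizes) >= n0)

    def test_zero_rate_is_infeasible(self):
        with pytest.raises(es.InfeasibleDesignError):
            es.sample_size(500.0, es.EventRateEstimate(0.0, 0.0, 0.0))


class TestScreenedAndCost:
    def test_screened_identity_exact(self):
        for n, t in [(3320, 0.5), (2360, 0.75), (1234.5, 0.35)]:
            assert es.total_screened(n, t) * (1 - t) == pytest.approx(n, rel=1e-15)

    def test_published_screened_values(self):
        assert es.total_screened(3320, 0.50) == pytest.approx(6640)
        assert es.total_screened(2360, 0.75) == pytest.approx(9440)
        assert es.total_screened(1000, 0.0) == 1000

    def test_threshold_one_rejected(self):
        with pytest.raises(ValueError):
            es.total_screened(100, 1.0)

    def test_constant_cost(self):
        costs = es.CostSpec(screening_cost=100, trial_cost=1000)
        assert es.total_cost(1000, 0.5, costs) == pytest.approx(1_200_000)
        free = es.CostSpec(screening_cost=0, trial_cost=1000)
        assert es.total_cost(1000, 0.9, free) == es.total_cost(1000, 0.0, free)

    def test_time_based_cost(self):
        costs = es.CostSpec(screening_cost=0, cost_per_time=100)
        assert es.total_cost(1000, 0.5, costs, expected_time_in_trial=40) == (
            pytest.approx(4_000_000)
        )
        with pytest.raises(ValueError):
            es.total_cost(1000, 0.5, costs)

    def test_cost_spec_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            es.CostSpec(screening_cost=10)
        with pytest.raises(ValueError):
            es.CostSpec(screening_cost=10, trial_cost=1, cost_per_time=1)

    def test_cost_reduction_sign_convention(self):
        assert es.cost_reduction(2_000_000, 2_000_000) == 0
        assert es.cost_reduction(1_500_000, 2_000_000) == pytest.approx(25)
        assert es.cost_reduction(2_200_000, 2_000_000) == pytest.approx(-10)


class TestBootstrap:
    def test_same_seed_reproducible(self, strong_marker_cohort):
        kwargs = dict(
            design=es.TrialDesign.accrual(12, 36), spec=es.TestingSpec(),
            threshold=0.5, statistic="event_rate", B=60, seed=42,
        )
        a = es.bootstrap_se(strong_marker_cohort, **kwargs)
        b = es.bootstrap_se(strong_marker_cohort, **kwargs)
        assert a == b

    def test_degenerate_data_has_zero_se(self):
        d = make_dataset(np.full(60, 36.0), np.zeros(60, dtype=int),
                         biomarker=np.arange(60, dtype=float))
        se = es.bootstrap_se(d, es.TrialDesign.accrual(6, 30), es.TestingSpec(),
                             0.0, "event_rate", B=50, seed=1)
        assert se == 0.0

    def test_agrees_with_delta_method_on_large_fixed_design(
        self, strong_marker_cohort
    ):
        curve = es.subgroup_curve(strong_marker_cohort, 0.0)
        s, se_s = es.survival_at(curve, 48.0)
        rates = es.event_rates_fixed(s, se_s, 0.8)
        n0 = es.events_required(es.TestingSpec())
        delta_sd_n = es.sample_size(n0, rates).sd_n
        boot_sd_n = es.bootstrap_se(
            strong_marker_cohort, es.TrialDesign.fixed(48), es.TestingSpec(),
            0.0, "sample_size", B=200, seed=7,
        )
        assert boot_sd_n == pytest.approx(delta_sd_n, rel=0.25)
        # and the control-arm rate SE vs the Greenwood SD it linearizes
        boot_er = es.bootstrap_se(
            strong_marker_cohort, es.TrialDesign.fixed(48), es.TestingSpec(),
            0.0, "event_rate", B=200, seed=7,
        )
        assert boot_er == pytest.approx(se_s, rel=0.25)

    def test_too_few_replicates_rejected(self, strong_marker_cohort):
        with pytest.raises(ValueError):
            es.bootstrap_se(strong_marker_cohort, es.TrialDesign.fixed(48),
                            es.TestingSpec(), 0.0, "event_rate", B=10, seed=1)
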