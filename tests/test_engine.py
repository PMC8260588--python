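"""Markov cohort engine: building blocks and whole-cohort invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clz_cea as cc
from clz_cea import engine
from clz_cea._slots import with_slot
from clz_cea.config import DEFAULT_CYCLE_DAYS, OnsetCurve, Strategy


class TestDiscountFactor:
    def test_zero_rate(self):
        assert engine.discount_factor(0.0, 57) == 1.0

    def test_one_year_at_two_percent(self):
        # 12 cycles of 365.25/12 days is exactly one year
        assert engine.discount_factor(0.02, 12) == pytest.approx(1 / 1.02, abs=1e-12)

    def test_cycle_zero(self):
        assert engine.discount_factor(0.035, 0) == 1.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            engine.discount_factor(-1.5, 1)


class TestDailyToCycleCost:
    @pytest.mark.parametrize(
        "daily,expected", [(4.42, 134.53), (1.23, 37.44), (0.0, 0.0)]
    )
    def test_examples(self, daily, expected):
        assert engine.daily_to_cycle_cost(daily, 30.4375) == pytest.approx(expected, abs=0.01)


class TestEffectiveOnsetCurve:
    def test_scaled_by_prevention_rate(self, jp_params):
        curve = OnsetCurve(cutoff=1500, monthly_onset_prob=[0.003, 0.002, 0.001])
        guided = Strategy(anc_cutoff=1500, hla_guided=True)
        out = engine.effective_onset_curve(curve, guided, jp_params.hla)
        assert out.monthly_onset_prob == pytest.approx([0.0021, 0.0014, 0.0007])

    def test_unguided_unchanged(self, jp_params):
        curve = jp_params.onset_curves[1500]
        unguided = Strategy(anc_cutoff=1500, hla_guided=False)
        assert engine.effective_onset_curve(curve, unguided, jp_params.hla) is curve

    @pytest.mark.parametrize("r,expect_zero", [(0.0, False), (1.0, True)])
    def test_degenerate_rates(self, jp_params, r, expect_zero):
        curve = jp_params.onset_curves[1500]
        guided = Strategy(anc_cutoff=1500, hla_guided=True)
        out = engine.effective_onset_curve(curve, guided, jp_params.hla, prevention_rate=r)
        if expect_zero:
            assert all(q == 0.0 for q in out.monthly_onset_prob)
        else:
            assert out.monthly_onset_prob == pytest.approx(curve.monthly_onset_prob)


class TestMonitoringStream:
    def test_first_cycle_has_four_weekly_tests(self, jp_params):
        stream = engine.monitoring_cost_stream(jp_params.country, True, 12)
        assert stream[0] == pytest.approx(4 * jp_params.country.per_test_cost)

    def test_biweekly_tail_mostly_two_tests(self, jp_params):
        stream = engine.monitoring_cost_stream(jp_params.country, True, 120)
        tail = stream[24:] / jp_params.country.per_test_cost
        assert set(np.round(tail).astype(int)) <= {2, 3}
        assert np.median(tail) == 2

    def test_zero_cost_or_off_clozapine(self, jp_params):
        assert engine.monitoring_cost_stream(jp_params.country, False, 12).sum() == 0.0
        free = jp_params.country.model_copy(update={"per_test_cost": 0.0})
        assert engine.monitoring_cost_stream(free, True, 12).sum() == 0.0

    @pytest.mark.parametrize("weeks,n_cycles", [(26, 120), (18, 60), (4, 24)])
    def test_day_resolution_event_list_oracle(self, jp_params, weeks, n_cycles):
        """Independent oracle: enumerate test days one by one and bin them."""
        cl = DEFAULT_CYCLE_DAYS
        country = jp_params.country.model_copy(update={"weekly_monitoring_weeks": weeks})
        counts = np.zeros(n_cycles)
        day, week = 0.0, 0
        while True:
            step = 7.0 if week < weeks else 14.0
            day += step
            week += 1 if step == 7.0 else 2
            if day > n_cycles * cl:
                break
            cycle = int(np.ceil(day / cl))
            counts[min(cycle, n_cycles) - 1] += 1
        stream = engine.monitoring_cost_stream(country, True, n_cycles)
        assert stream == pytest.approx(counts * country.per_test_cost)


def _zero_onset(params):
    out = params.model_copy(deep=True)
    n = len(out.onset_curves[1500].monthly_onset_prob)
    out.onset_curves = {
        1500: OnsetCurve(cutoff=1500, monthly_onset_prob=[0.0] * n)
    }
    return out


class TestRunCohort:
    def test_no_transitions_closed_form(self, jp_params):
        """q = 0, no discounting, 1 year: cost is drug + monitoring, QALYs equal
        the clozapine utility exactly."""
        params = _zero_onset(jp_params)
        params.country.annual_discount_rate = 0.0
        params.horizon_years = 1.0
        unguided = Strategy(anc_cutoff=1500, hla_guided=False)
        _, outcome = cc.run_cohort(unguided, params)
        monitoring = engine.monitoring_cost_stream(params.country, True, 12).sum()
        assert outcome.discounted_cost == pytest.approx(
            365.25 * params.country.clz_daily_cost + monitoring, abs=1e-9
        )
        assert outcome.discounted_qalys == pytest.approx(params.country.utility_clz, abs=1e-12)

    def test_constant_hazard_geometric_series(self, jp_params):
        """Expected cycles on clozapine at constant q, zero discount, equals
        (1 - (1-q)^N) / q."""
        q, years = 0.01, 10
        params = jp_params.model_copy(deep=True)
        params.country.annual_discount_rate = 0.0
        params.horizon_years = float(years)
        n = years * 12
        params.onset_curves = {1500: OnsetCurve(cutoff=1500, monthly_onset_prob=[q] * n)}
        trace, _ = cc.run_cohort(Strategy(anc_cutoff=1500, hla_guided=False), params)
        on_clz_cycles = trace.occupancy[:-1, 0].sum()  # membership at cycle start
        assert on_clz_cycles == pytest.approx((1 - (1 - q) ** n) / q, abs=1e-9)

    def test_occupancy_conservation_and_incidence_identity(self, jp_params, base_pair):
        trace, _ = cc.run_cohort(base_pair[0], jp_params)
        assert trace.occupancy.sum(axis=1) == pytest.approx(1.0, abs=1e-12)
        decrease = trace.occupancy[:-1, 0] - trace.occupancy[1:, 0]
        assert trace.incident_ciag == pytest.approx(decrease, abs=1e-15)
        assert np.all(np.diff(trace.occupancy[:, 1]) >= 0)  # absorbing substitute

    def test_arm_identity_at_zero_prevention_and_test_cost(self, jp_params, base_pair):
        guided, unguided = base_pair
        params = with_slot(jp_params, "prevention_rate", 0.0)
        params = with_slot(params, "hla_test_cost", 0.0)
        trace_g, out_g = cc.run_cohort(guided, params)
        trace_u, out_u = cc.run_cohort(unguided, params)
        assert out_g.discounted_cost == out_u.discounted_cost
        assert out_g.discounted_qalys == out_u.discounted_qalys
        assert np.array_equal(trace_g.occupancy, trace_u.occupancy)

    def test_prevention_monotonicity(self, jp_params):
        guided = Strategy(anc_cutoff=1500, hla_guided=True)
        prev_qalys, prev_nontest = -np.inf, np.inf
        for r in (0.0, 0.2, 0.5, 0.8, 1.0):
            _, out = cc.run_cohort(guided, with_slot(jp_params, "prevention_rate", r))
            nontest = out.discounted_cost - out.cost_breakdown["hla_test"]
            assert out.discounted_qalys >= prev_qalys
            assert nontest <= prev_nontest
            prev_qalys, prev_nontest = out.discounted_qalys, nontest

    def test_discount_monotonicity(self, uk_params, base_pair):
        costs, qalys = [], []
        for rate in (0.0, 0.02, 0.035, 0.06):
            _, out = cc.run_cohort(base_pair[1], with_slot(uk_params, "discount_rate", rate))
            costs.append(out.discounted_cost)
            qalys.append(out.discounted_qalys)
        assert all(a >= b for a, b in zip(costs, costs[1:]))
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))

    def test_breakdown_sums_and_discount_bounds(self, jp_params, base_pair):
        _, out = cc.run_cohort(base_pair[0], jp_params)
        assert sum(out.cost_breakdown.values()) == pytest.approx(out.discounted_cost, rel=1e-12)
        assert all(v >= 0 for v in out.cost_breakdown.values())
        assert out.discounted_cost <= out.undiscounted_cost
        assert out.discounted_qalys <= out.undiscounted_qalys
        assert out.discounted_qalys <= jp_params.horizon_years * jp_params.country.utility_clz

    def test_half_cycle_correction_shrinks_clozapine_time(self, jp_params, base_pair):
        params = jp_params.model_copy(deep=True)
        params.half_cycle_correction = True
        _, out_hcc = cc.run_cohort(base_pair[1], params)
        _, out_std = cc.run_cohort(base_pair[1], jp_params)
        assert out_hcc.discounted_qalys <= out_std.discounted_qalys

    def test_missing_curve_raises(self, jp_params):
        params = jp_params.model_copy(deep=True)
        params.onset_curves = {1500: params.onset_curves[1500]}
        with pytest.raises(cc.ConfigError, match="500"):
            cc.run_cohort(Strategy(anc_cutoff=500, hla_guided=False), params)


@given(
    q_scale=st.floats(min_value=0.0, max_value=1.0),
    years=st.integers(min_value=1, max_value=15),
    rate=st.floats(min_value=0.0, max_value=0.1),
)
@settings(max_examples=25, deadline=None)
def test_conservation_property(q_scale, years, rate):
    """Occupancy rows sum to one for arbitrary hazards, horizons, discounts."""
    params = cc.study_fixture("JPN")
    params = with_slot(params, "discount_rate", rate)
    params.horizon_years = float(years)
    base = np.asarray(params.onset_curves[1500].monthly_onset_prob)
    params.onset_curves[1500] = OnsetCurve(
        cutoff=1500, monthly_onset_prob=(base * q_scale).tolist()
    )
    trace, out = cc.run_cohort(Strategy(anc_cutoff=1500, hla_guided=True), params)
    assert trace.occupancy.sum(axis=1) == pytest.approx(1.0, abs=1e-12)
    assert out.discounted_cost >= 0 and out.discounted_qalys >= 0
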