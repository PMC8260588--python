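"""Parameter sampling, Monte Carlo propagation, CEAC, and percentiles."""

import numpy as np
import pytest

import clz_cea as cc
from clz_cea.psa import (
    DistributionSpec,
    PSAResult,
    _rng_for,
    ceac,
    default_psa_specs,
    percentile_interval,
    run_psa,
    sample_parameters,
)


class TestPercentileInterval:
    def test_order_statistic_interpolation(self):
        lo, hi = percentile_interval(np.arange(1, 101))
        assert lo == pytest.approx(3.475, abs=1e-12)
        assert hi == pytest.approx(97.525, abs=1e-12)

    def test_constant_samples(self):
        assert percentile_interval([4.2, 4.2, 4.2]) == (4.2, 4.2)

    def test_errors(self):
        with pytest.raises(ValueError):
            percentile_interval([1.0])
        with pytest.raises(ValueError):
            percentile_interval([1.0, 2.0], lo=0.9, hi=0.1)


class TestDistributionSpec:
    def test_family_slot_mismatch_rejected_at_load(self):
        with pytest.raises(ValueError, match="beta"):
            DistributionSpec(name="ciag_treatment_cost", family="beta", mean=0.5, ci=(0.2, 0.8))
        with pytest.raises(ValueError, match="gamma"):
            DistributionSpec(name="utility_clz", family="gamma", mean=0.7, ci=(0.6, 0.8))

    def test_unknown_slot_rejected(self):
        with pytest.raises(ValueError, match="valid names"):
            DistributionSpec(name="mystery", family="fixed")

    def test_ci_order_checked(self):
        with pytest.raises(ValueError):
            DistributionSpec(name="prevention_rate", family="beta", mean=0.3, ci=(0.8, 0.2))

    def test_infeasible_beta_moments_rejected_at_load(self):
        with pytest.raises(ValueError, match="infeasible"):
            DistributionSpec(name="prevention_rate", family="beta", mean=0.5, ci=(-3.0, 4.0))

    def test_beta_moment_match_recovers_mean(self):
        spec = DistributionSpec(name="prevention_rate", family="beta", mean=0.30, ci=(0.2, 0.8))
        draws = spec.draw(np.random.default_rng(0), 200_000, 0.30)
        assert np.all((draws >= 0) & (draws <= 1))
        sd = (0.8 - 0.2) / 3.92
        assert np.mean(draws) == pytest.approx(0.30, abs=4 * sd / np.sqrt(200_000))

    def test_gamma_moment_match_recovers_mean(self):
        spec = DistributionSpec(
            name="ciag_treatment_cost", family="gamma", mean=985.8, ci=(700.0, 1300.0)
        )
        draws = spec.draw(np.random.default_rng(1), 200_000, 985.8)
        assert np.all(draws >= 0)
        assert np.mean(draws) == pytest.approx(985.8, rel=0.01)


class TestSampling:
    def test_all_fixed_returns_base(self, jp_params):
        specs = [
            DistributionSpec(name="prevention_rate", family="fixed"),
            DistributionSpec(name="clz_daily_cost", family="fixed"),
        ]
        sampled = sample_parameters(specs, jp_params, seed=3)
        assert sampled == jp_params

    def test_seed_reproducibility(self, jp_params):
        specs = default_psa_specs(jp_params)
        a = sample_parameters(specs, jp_params, seed=42)
        b = sample_parameters(specs, jp_params, seed=42)
        assert a == b
        c = sample_parameters(specs, jp_params, seed=43)
        assert c != a

    def test_substreams_independent_of_spec_list(self, jp_params):
        """Adding a spec must not reorder another parameter's draw stream."""
        only_prev = [DistributionSpec(name="prevention_rate", family="beta", mean=0.3, ci=(0.2, 0.8))]
        both = only_prev + [
            DistributionSpec(name="clz_daily_cost", family="gamma", mean=4.42, ci=(3.0, 6.0))
        ]
        a = sample_parameters(only_prev, jp_params, seed=5)
        b = sample_parameters(both, jp_params, seed=5)
        assert a.hla.prevention_rate == b.hla.prevention_rate

    def test_draws_respect_invariants(self, jp_params):
        spec = DistributionSpec(name="utility_substitute", family="beta", mean=0.56, ci=(0.3, 0.8))
        draws = spec.draw(_rng_for(9, spec.name), 5_000, 0.56)
        assert np.all((draws >= 0) & (draws <= 1))


class TestRunPSA:
    def test_degenerate_specs_collapse_to_point_estimate(self, jp_params, base_pair):
        specs = [DistributionSpec(name="prevention_rate", family="fixed")]
        result = run_psa(specs, jp_params, base_pair, n_iterations=8, seed=0)
        _, out_g = cc.run_cohort(base_pair[0], jp_params)
        _, out_u = cc.run_cohort(base_pair[1], jp_params)
        assert np.all(result.cost_comparator == out_g.discounted_cost)
        assert np.all(result.qalys_reference == out_u.discounted_qalys)
        point_icer = (out_g.discounted_cost - out_u.discounted_cost) / (
            out_g.discounted_qalys - out_u.discounted_qalys
        )
        assert result.mean_icer == pytest.approx(point_icer, rel=1e-12)
        lo, hi = result.intervals()["cost_comparator"]
        assert lo == hi == pytest.approx(out_g.discounted_cost)

    def test_bit_identical_reruns(self, jp_params, base_pair):
        specs = default_psa_specs(jp_params)
        a = run_psa(specs, jp_params, base_pair, n_iterations=50, seed=7)
        b = run_psa(specs, jp_params, base_pair, n_iterations=50, seed=7)
        assert np.array_equal(a.cost_comparator, b.cost_comparator)
        assert np.array_equal(a.delta_qalys, b.delta_qalys)
        assert a.to_dict() == b.to_dict()

    def test_summaries_scale_with_iteration_count(self, jp_params, base_pair):
        """Means at different n agree within Monte Carlo error."""
        specs = default_psa_specs(jp_params)
        small = run_psa(specs, jp_params, base_pair, n_iterations=200, seed=2)
        large = run_psa(specs, jp_params, base_pair, n_iterations=800, seed=3)
        se = np.std(small.delta_cost, ddof=1) / np.sqrt(200)
        assert np.mean(small.delta_cost) == pytest.approx(
            np.mean(large.delta_cost), abs=5 * se
        )

    def test_scatter_row_count_and_intervals_bracket_mean(self, jp_params, base_pair):
        specs = default_psa_specs(jp_params)
        result = run_psa(specs, jp_params, base_pair, n_iterations=120, seed=4)
        assert len(result.scatter()) == 120
        iv = result.intervals()
        assert iv["cost_comparator"][0] <= np.mean(result.cost_comparator) <= iv["cost_comparator"][1]
        assert 0.0 <= result.acceptance_probability <= 1.0

    def test_invalid_iteration_count(self, jp_params, base_pair):
        with pytest.raises(ValueError):
            run_psa([], jp_params, base_pair, n_iterations=0, seed=0)


def _manual_result(delta_cost, delta_qalys, wtp=30000.0):
    n = len(delta_cost)
    zeros = np.zeros(n)
    return PSAResult(
        n_iterations=n,
        seed=0,
        comparator=cc.Strategy(anc_cutoff=1500, hla_guided=True),
        reference=cc.Strategy(anc_cutoff=1500, hla_guided=False),
        wtp=wtp,
        cost_comparator=np.asarray(delta_cost, dtype=float),
        qalys_comparator=np.asarray(delta_qalys, dtype=float),
        cost_reference=zeros,
        qalys_reference=zeros,
    )


class TestCEAC:
    def test_equals_brute_force_count(self):
        dc = [10.0, -5.0, 40.0, 3.0]
        dq = [0.001, 0.002, -0.001, 0.0005]
        result = _manual_result(dc, dq)
        grid = [0.0, 5000.0, 20000.0, 60000.0]
        curve = ceac(result, grid)
        for wtp, prob in zip(curve.wtp, curve.probability):
            expected = np.mean([wtp * q - c > 0 for c, q in zip(dc, dq)])
            assert prob == pytest.approx(expected)

    def test_zero_wtp_is_cost_saving_fraction(self):
        dc = [10.0, -5.0, -1.0]
        result = _manual_result(dc, [0.01, 0.01, 0.01])
        assert ceac(result, [0.0]).probability.iloc[0] == pytest.approx(2 / 3)

    def test_large_wtp_limit_is_qaly_gain_fraction(self):
        dq = [0.01, -0.02, 0.03, 0.05]
        result = _manual_result([1.0, 1.0, 1.0, 1.0], dq)
        assert ceac(result, [1e12]).probability.iloc[0] == pytest.approx(3 / 4)

    def test_monotone_when_all_qaly_gains_positive(self):
        rng = np.random.default_rng(0)
        result = _manual_result(rng.normal(50, 30, 200), rng.uniform(0.001, 0.01, 200))
        curve = ceac(result, np.linspace(0, 100000, 25))
        assert np.all(np.diff(curve.probability) >= 0)

    def test_grid_validation(self):
        result = _manual_result([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            ceac(result, [])
        with pytest.raises(ValueError):
            ceac(result, [100.0, 50.0])
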