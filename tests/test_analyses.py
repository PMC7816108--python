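"""Tests for sensitivity, threshold, scenario and subgroup analyses."""

import numpy as np
import pytest

from hcc_cea.analyses import (
    ICER_CAP,
    ParameterSpec,
    one_way,
    psa,
    run_scenario,
    subgroup,
    threshold_price,
    two_way,
)


def spec_of(path, base, low=None, high=None, dist=None):
    return ParameterSpec(path=path, base=base, low=base if low is None else low,
                         high=base if high is None else high, distribution=dist)


class TestOneWay:
    def test_degenerate_range_zero_spread(self, base_model):
        rows = one_way([spec_of("pembrolizumab.drug_cost_per_cycle", 6915.0)], base_model)
        assert rows[0].spread == 0.0

    def test_price_monotonicity(self, base_model):
        rows = one_way([spec_of("pembrolizumab.drug_cost_per_cycle", 6915.0, 5531.0, 8297.0)], base_model)
        assert rows[0].icer_at_low < rows[0].icer_at_high

    def test_rows_sorted_by_spread(self, base_config):
        rows = one_way(base_config.specs, base_config.model)
        spreads = [r.spread for r in rows]
        assert spreads == sorted(spreads, reverse=True)

    def test_unresolvable_path_raises(self, base_model):
        with pytest.raises(KeyError):
            one_way([spec_of("pembrolizumab.nonexistent", 1.0)], base_model)


class TestTwoWay:
    def test_degenerate_ranges_give_constant_grid(self, base_model):
        a = spec_of("pembrolizumab.drug_cost_per_cycle", 6915.0)
        b = spec_of("placebo.utility_pf", 0.76)
        _, _, grid, _ = two_way(a, b, base_model, grid_n=3)
        assert np.allclose(grid, grid[0, 0])

    def test_swapping_parameters_transposes_grid(self, base_model):
        a = spec_of("pembrolizumab.drug_cost_per_cycle", 6915.0, 5531.0, 8297.0)
        b = spec_of("placebo.utility_pf", 0.76, 0.59, 0.93)
        _, _, g1, _ = two_way(a, b, base_model, grid_n=3)
        _, _, g2, _ = two_way(b, a, base_model, grid_n=3)
        assert np.allclose(g1, g2.T)

    def test_os_median_advantage_structure(self, base_model):
        # ICER falls monotonically as the intervention's median OS advantage
        # grows, and a willingness-to-pay crossing exists within the grid
        a = spec_of("pembrolizumab.median_os", 13.9, 10.6, 24.6)
        b = spec_of("placebo.utility_pf", 0.76, 0.59, 0.93)
        a_vals, _, grid, ce = two_way(a, b, base_model, grid_n=8, wtp=150_000.0)
        mid_col = grid[:, 4]
        assert np.all(np.diff(mid_col) < 0)
        assert ce.any() and not ce.all()

    def test_grid_n_validated(self, base_model):
        a = spec_of("pembrolizumab.drug_cost_per_cycle", 6915.0)
        with pytest.raises(ValueError):
            two_way(a, a, base_model, grid_n=1)


class TestPSA:
    def test_zero_variance_reproduces_base_case(self, base_model, base_result):
        specs = [spec_of("pembrolizumab.drug_cost_per_cycle", 6915.0, dist="gamma")]
        res = psa(specs, base_model, n_draws=20, seed=3)
        assert np.allclose(res.delta_cost, base_result.delta_cost)
        assert np.allclose(res.delta_qaly, base_result.delta_qaly)
        # CEAC is a step function at the base-case ICER
        icer = base_result.icer_per_qaly
        assert res.prob_cost_effective(icer * 0.9) == 0.0
        assert res.prob_cost_effective(icer * 1.1) == 1.0

    def test_same_seed_identical_different_seed_close(self, base_config):
        m, specs = base_config.model, base_config.specs
        r1 = psa(specs, m, n_draws=400, seed=10)
        r2 = psa(specs, m, n_draws=400, seed=10)
        r3 = psa(specs, m, n_draws=400, seed=11)
        assert np.array_equal(r1.delta_cost, r2.delta_cost)
        for wtp in (200_000.0, 300_000.0):
            assert abs(r1.prob_cost_effective(wtp) - r3.prob_cost_effective(wtp)) < 3.0 / np.sqrt(400)

    def test_ceac_limits(self, base_config):
        res = psa(base_config.specs, base_config.model, n_draws=300, seed=5)
        assert res.prob_cost_effective(0.0) == pytest.approx(np.mean(res.delta_cost < 0.0))
        assert res.prob_cost_effective(1e12) == pytest.approx(np.mean(res.delta_qaly > 0.0))

    def test_ceac_monotone_in_wtp(self, base_config):
        res = psa(base_config.specs, base_config.model, n_draws=300, seed=6)
        probs = [p.prob_cost_effective for p in res.ceac]
        assert np.all(np.diff(probs) >= -1e-12)

    def test_beta_draws_respect_domain(self, base_config):
        res = psa(base_config.specs, base_config.model, n_draws=500, seed=7)
        assert np.isfinite(res.delta_cost).all() and np.isfinite(res.delta_qaly).all()

    def test_missing_distribution_rejected(self, base_model):
        with pytest.raises(ValueError, match="distribution"):
            psa([spec_of("pembrolizumab.drug_cost_per_cycle", 6915.0)], base_model, n_draws=5, seed=1)


class TestThreshold:
    def test_affine_cost_inversion(self, base_model):
        # incremental cost is affine in the per-cycle price with fixed
        # incremental QALY, so the bisection must match the closed form
        path = "pembrolizumab.drug_cost_per_cycle"
        r0 = base_model.set_param(path, 0.0).run()
        r1 = base_model.set_param(path, 1000.0).run()
        slope = (r1.delta_cost - r0.delta_cost) / 1000.0
        dq = r0.delta_qaly
        target = 150_000.0
        analytic = (target * dq - r0.delta_cost) / slope
        price, reduction = threshold_price(base_model, target_wtp=target, tol=1e-4)
        assert price == pytest.approx(analytic, abs=0.01)
        assert reduction == pytest.approx(100.0 * (6915.0 - analytic) / 6915.0, abs=0.01)

    def test_target_equal_to_base_icer_returns_base_price(self, base_model, base_result):
        price, reduction = threshold_price(
            base_model, target_wtp=base_result.icer_per_qaly, bracket=(0.0, 13_830.0), tol=1e-4
        )
        assert price == pytest.approx(6915.0, abs=0.5)
        assert abs(reduction) < 0.01

    def test_post_hoc_icer_within_tolerance(self, base_model):
        price, _ = threshold_price(base_model, target_wtp=150_000.0)
        res = base_model.set_param("pembrolizumab.drug_cost_per_cycle", price).run()
        assert res.icer_per_qaly == pytest.approx(150_000.0, abs=1.0)

    def test_invalid_bracket_raises(self, base_model):
        with pytest.raises(ValueError, match="bracket"):
            threshold_price(base_model, target_wtp=1_000.0)  # ICER(0) already above


class TestScenarios:
    def test_three_year_horizon_is_identity(self, base_model, base_result):
        res = run_scenario("horizon", base_model, horizon_years=3.0)
        assert res.icer_per_qaly == pytest.approx(base_result.icer_per_qaly, rel=1e-12)

    def test_cure_lowers_icer(self, base_model, base_result):
        res = run_scenario("cure_30mo", base_model)
        assert res.icer_per_qaly < base_result.icer_per_qaly

    def test_longer_horizons_monotonically_lower_icer(self, base_model, base_result):
        icers = [base_result.icer_per_qaly]
        for years in (5.0, 10.0, None):
            icers.append(run_scenario("horizon", base_model, horizon_years=years).icer_per_qaly)
        assert np.all(np.diff(icers) < 0)

    def test_alternative_schedule_halves_admin_only(self, base_model, base_result):
        res = run_scenario("dose_400q6w", base_model)
        assert res.delta_cost < base_result.delta_cost
        assert res.delta_qaly == pytest.approx(base_result.delta_qaly)

    def test_unknown_scenario_rejected(self, base_model):
        with pytest.raises(ValueError, match="scenario"):
            run_scenario("cure_12mo", base_model)


class TestSubgroup:
    def test_null_hazard_ratio_removes_survival_benefit(self, base_model):
        res = subgroup(1.0, base_model)
        assert abs(res.delta_ly) < 0.01
        assert res.dominance == "intervention dominated" or res.icer_per_qaly > 1_000_000.0

    def test_base_hazard_ratio_recovers_base_orientation(self, base_model, base_result):
        res = subgroup(0.78, base_model)
        assert res.icer_per_qaly == pytest.approx(base_result.icer_per_qaly, rel=0.05)

    def test_icer_increases_with_hazard_ratio(self, base_model):
        icers = [min(subgroup(hr, base_model).icer_per_qaly or ICER_CAP, ICER_CAP)
                 for hr in np.linspace(0.61, 1.0, 6)]
        assert np.all(np.diff(icers) > 0)

    def test_nonpositive_hr_rejected(self, base_model):
        with pytest.raises(ValueError):
            subgroup(0.0, base_model)
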