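"""Tests for the 3-state Markov cohort engine."""

import numpy as np
import pytest
from scipy.integrate import quad

from hcc_cea.markov_engine import (
    DAYS_PER_MONTH,
    ModelConfig,
    background_mortality,
    build_trace,
    cycle_probability,
    life_years,
)
from hcc_cea.parametric_survival import ParametricSurvival, calibrate_weibull
from hcc_cea.synthetic_data import LifeTable, default_life_table

IMMORTAL = ParametricSurvival("exponential", {"scale": 1e12})
DOOMED = ParametricSurvival("exponential", {"scale": 1e-6})


class TestCycleProbability:
    def test_arithmetic(self):
        # S(t)=0.8 -> S(t+d)=0.6 gives conditional exit 0.25
        c = ParametricSurvival("weibull", {"shape": 1.0, "scale": 1.0})
        t = -np.log(0.8)  # S(t)=0.8 for unit-scale exponential
        d = -np.log(0.6) - t
        assert cycle_probability(c, t, d) == pytest.approx(0.25, rel=1e-12)

    def test_exponential_is_memoryless(self):
        c = ParametricSurvival("exponential", {"scale": 10.0})
        vals = [cycle_probability(c, t, 0.7) for t in (0.0, 3.0, 11.0, 29.0)]
        assert np.allclose(vals, 1.0 - np.exp(-0.7 / 10.0))

    def test_decreasing_hazard_weibull_decreases_on_grid(self):
        c = ParametricSurvival("weibull", {"shape": 0.9, "scale": 20.0})
        probs = [cycle_probability(c, t, 0.69) for t in np.arange(0.5, 36.0, 0.69)]
        assert np.all(np.diff(probs) < 0)


class TestBackgroundMortality:
    def test_zero_probability(self, flat_life_table):
        assert background_mortality(flat_life_table, 70.0, 0.69) == 0.0

    def test_formula(self):
        lt = LifeTable(np.array([62]), np.array([0.012]))
        dm = 21.0 / DAYS_PER_MONTH
        assert background_mortality(lt, 62.4, dm) == pytest.approx(
            1.0 - 0.988 ** (dm / 12.0), rel=1e-12
        )

    def test_age_beyond_table_uses_last_row(self):
        lt = default_life_table()
        assert background_mortality(lt, 130.0, 1.0) == background_mortality(lt, 100.0, 1.0)


class TestBuildTrace:
    def test_occupancy_conservation(self, base_model):
        t = build_trace(
            base_model.intervention.os_curve,
            base_model.intervention.pfs_curve,
            base_model.life_table,
            base_model.config,
        )
        assert np.max(np.abs(t.pf + t.pp + t.dead - 1.0)) <= 1e-9
        assert np.all(t.pf >= 0) and np.all(t.pp >= 0) and np.all(t.dead >= 0)
        assert np.all(np.diff(t.dead) >= -1e-15)
        assert t.discount[0] == 1.0 and np.all(np.diff(t.discount) < 0)

    def test_immortal_cohort_stays_progression_free(self, flat_life_table):
        cfg = ModelConfig(discount_rate_annual=0.0)
        t = build_trace(IMMORTAL, IMMORTAL, flat_life_table, cfg)
        assert np.allclose(t.pf, 1.0) and np.allclose(t.dead, 0.0)
        assert life_years(t, discounted=False) == pytest.approx(3.0, abs=1e-9)

    def test_certain_death_in_first_cycle(self, flat_life_table):
        t = build_trace(DOOMED, DOOMED, flat_life_table, ModelConfig())
        assert np.allclose(t.dead[1:], 1.0)
        assert life_years(t, discounted=False) < 0.05

    def test_alive_total_reproduces_os_curve(self, base_model):
        # death hazard taken from OS for both states: the alive trace is the
        # OS law evaluated at cycle boundaries (background floor rarely binds)
        cfg = base_model.config
        os_c = base_model.intervention.os_curve
        t = build_trace(os_c, base_model.intervention.pfs_curve, base_model.life_table, cfg)
        assert np.allclose(t.alive, os_c.survival(t.time_months), atol=1e-9)

    def test_undiscounted_ly_matches_weibull_rmst(self, base_model, flat_life_table):
        os_c = calibrate_weibull(13.9, landmark=(30.0, 0.25))
        cfg = ModelConfig(discount_rate_annual=0.0)
        t = build_trace(os_c, base_model.intervention.pfs_curve, flat_life_table, cfg)
        rmst = quad(lambda x: os_c.survival(x), 0.0, 36.0, limit=200)[0] / 12.0
        assert life_years(t, discounted=False) == pytest.approx(rmst, rel=0.02)

    def test_discounted_annuity_limit(self, flat_life_table):
        # immortal cohort, 1-year horizon: discounted LY ~ annuity integral
        cfg = ModelConfig(horizon_years=1.0, discount_rate_annual=0.03)
        t = build_trace(IMMORTAL, IMMORTAL, flat_life_table, cfg)
        expected = (1.0 - 1.03**-1) / np.log(1.03)
        assert life_years(t, discounted=True) == pytest.approx(expected, rel=0.01)

    def test_exponential_quadrature_limit(self, flat_life_table):
        # zero background, exponential OS: discounted LY vs closed-form integral
        os_c = ParametricSurvival("exponential", {"scale": 14.0})
        cfg = ModelConfig(discount_rate_annual=0.03)
        t = build_trace(os_c, os_c, flat_life_table, cfg)
        target = quad(lambda x: os_c.survival(x) * 1.03 ** (-x / 12.0), 0.0, 36.0)[0] / 12.0
        assert life_years(t, discounted=True) == pytest.approx(target, rel=0.01)

    def test_cure_scenario_death_equals_background_exactly(self, base_model):
        cfg = ModelConfig(cure_scenario=True, cure_time_months=30.0, horizon_years=3.0)
        m = base_model
        t = build_trace(m.intervention.os_curve, m.intervention.pfs_curve, m.life_table, cfg)
        dm = cfg.cycle_months
        for c in range(t.n_cycles):
            tc = t.time_months[c]
            if tc >= 30.0 and t.alive[c] > 0:
                p_death = t.new_dead[c] / t.alive[c]
                bg = background_mortality(m.life_table, cfg.start_age_years + tc / 12.0, dm)
                assert p_death == pytest.approx(bg, rel=1e-9)

    def test_raising_mortality_never_increases_life_years(self, base_model, flat_life_table):
        cfg = ModelConfig()
        pfs = base_model.intervention.pfs_curve
        scales = [25.0, 20.0, 15.0, 10.0, 5.0]
        lys = [
            life_years(build_trace(ParametricSurvival("weibull", {"shape": 0.9, "scale": s}), pfs, flat_life_table, cfg))
            for s in scales
        ]
        assert np.all(np.diff(lys) < 0)

    def test_half_cycle_correction_bound(self, base_model):
        m = base_model
        t_on = build_trace(m.intervention.os_curve, m.intervention.pfs_curve, m.life_table, ModelConfig(half_cycle_correction=True))
        t_off = build_trace(m.intervention.os_curve, m.intervention.pfs_curve, m.life_table, ModelConfig(half_cycle_correction=False))
        diff = abs(life_years(t_on, False) - life_years(t_off, False))
        # trapezoid vs left endpoint differ by at most half the total occupancy change
        bound = 0.5 * (t_off.alive[0] - t_off.alive[-1]) * t_off.config.cycle_months / 12.0
        assert diff <= bound + 1e-12

    def test_lifetime_horizon_terminates(self, base_model):
        cfg = ModelConfig(horizon_years=None)
        t = build_trace(base_model.reference.os_curve, base_model.reference.pfs_curve, base_model.life_table, cfg)
        assert t.alive[-1] < 1e-6 or cfg.start_age_years + t.time_months[-1] / 12.0 >= 100.0

    def test_trace_export_columns(self, base_model):
        m = base_model
        df = build_trace(m.reference.os_curve, m.reference.pfs_curve, m.life_table, m.config).to_frame()
        assert list(df.columns) == ["cycle", "time_months", "pf", "pp", "dead", "on_treatment", "discount"]
        assert len(df) == 54  # 53 cycles of 21 days cover 36 months, plus the terminal row

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(horizon_years=-1.0)
        with pytest.raises(ValueError):
            ModelConfig(discount_rate_annual=1.5)
        with pytest.raises(ValueError):
            ModelConfig(background_mode="multiply")
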