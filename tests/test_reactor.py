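"""Batch STR and two-stage cascade mass balances."""

import numpy as np
import pytest

from ferrokin.rates import RateLaw, mean_rate, BioreductionSeries
from ferrokin.reactor import (
    BatchConfig,
    GrowthReactorConfig,
    ReductionReactorConfig,
    hydraulic_residence_time,
    simulate_batch,
    simulate_cascade,
    simulate_growth_reactor,
    simulate_reduction_reactor,
    steady_state,
    volumetric_reduction_rate,
)


class TestHRT:
    def test_pilot_bioreduction_reactor(self):
        assert hydraulic_residence_time(4.0, 29.5) == pytest.approx(135.6, abs=0.1)

    def test_pilot_growth_reactor_implied(self):
        # 2 L at 26.5 mL·h⁻¹ implies 75.5 h (the nominal 70 h is not
        # consistent with these figures; the implied value is reported)
        assert hydraulic_residence_time(2.0, 26.5) == pytest.approx(75.5, abs=0.1)

    def test_unit_identity(self):
        assert hydraulic_residence_time(3.0, 3000.0) == pytest.approx(1.0)

    def test_zero_inflow_rejected(self):
        with pytest.raises(ValueError):
            hydraulic_residence_time(2.0, 0.0)


class TestBatch:
    def test_linear_depletion_closed_form(self):
        cfg = BatchConfig(fe3_0=4500.0, biomass=1e9, rate_law=RateLaw(0.0, 2.0),
                          duration=2600.0, step=100.0)
        sim = simulate_batch(cfg)
        active = sim.times <= 2200.0
        np.testing.assert_allclose(sim["fe2"][active], 2.0 * sim.times[active],
                                   rtol=1e-7, atol=1e-6)
        # after exhaustion at t = 2250 h the trace is flat at the inventory
        assert sim["fe2"][-1] == pytest.approx(4500.0, rel=1e-6)
        assert sim["fe3"][-1] == pytest.approx(0.0, abs=1e-3)

    def test_iron_conservation_without_precipitation(self):
        cfg = BatchConfig(fe3_0=4500.0, fe2_0=100.0, biomass=2e9, duration=288.0)
        sim = simulate_batch(cfg)
        np.testing.assert_allclose(sim["fe2"] + sim["fe3"], 4600.0, rtol=1e-9)
        assert sim.diagnostics["iron_balance"] < 1e-9

    def test_iron_conservation_with_precipitation_sink(self):
        cfg = BatchConfig(fe3_0=4500.0, biomass=2e9, k_precip=5e-3, duration=288.0)
        sim = simulate_batch(cfg)
        inventory = sim["fe2"] + sim["fe3"] + sim["fe_precip"]
        np.testing.assert_allclose(inventory, 4500.0, rtol=1e-9)
        assert sim["fe_precip"][-1] > 0

    def test_estimator_recovers_configured_rate(self):
        law = RateLaw(3.46e-9, 1.55)
        cfg = BatchConfig(fe3_0=4500.0, biomass=2e9, rate_law=law, duration=288.0)
        sim = simulate_batch(cfg)
        series = BioreductionSeries(times=sim.times, fe2=sim["fe2"])
        assert mean_rate(series) == pytest.approx(float(law(2e9)), rel=1e-6)

    def test_states_nonnegative(self):
        cfg = BatchConfig(fe3_0=500.0, biomass=5e9, duration=500.0, step=5.0)
        sim = simulate_batch(cfg)
        for name, traj in sim.states.items():
            assert np.all(traj >= 0.0), name


class TestGrowthReactor:
    def test_pure_cstr_nutrients_relax_to_inlet(self):
        cfg = GrowthReactorConfig(growth_rate=0.0, inlet={"NH4+": 127.0})
        sim = simulate_growth_reactor(cfg, duration=1500.0, x0=0.0)
        assert sim["NH4+"][-1] == pytest.approx(127.0, rel=1e-6)
        assert sim["biomass"][-1] == 0.0

    def test_chemostat_steady_state_algebra(self):
        cfg = GrowthReactorConfig()
        sim = simulate_growth_reactor(cfg, duration=3000.0)
        mu, k, hrt = cfg.growth_rate, cfg.carrying_capacity, cfg.hrt
        assert mu * hrt > 1.0
        x_star = k * (1.0 - 1.0 / (mu * hrt))
        assert sim["biomass"][-1] == pytest.approx(x_star, rel=1e-6)
        # growth exactly balances dilution at steady state
        assert mu * (1.0 - x_star / k) == pytest.approx(1.0 / hrt, rel=1e-12)

    def test_stage1_ammonium_outlet(self):
        # uptake tuned to 0.104 mmol·h⁻¹ at 2e9 cells·mL⁻¹ gives outlet
        # ≈59 mg·L⁻¹ from inlet 127 at HRT 73 h
        q = 0.104 * 18.04 / 2.0 / 2e9
        cfg = GrowthReactorConfig(inflow=2000.0 / 73.0, uptake_per_cell={"NH4+": q})
        sim = simulate_growth_reactor(cfg, duration=4000.0)
        assert sim.steady_state["biomass"] == pytest.approx(2e9, rel=0.01)
        assert sim.steady_state["NH4+"] == pytest.approx(59.0, abs=1.0)
        assert sim["NH4+"][-1] == pytest.approx(sim.steady_state["NH4+"], rel=1e-4)

    def test_washout_when_growth_below_dilution(self):
        cfg = GrowthReactorConfig(growth_rate=0.005)  # µ·HRT ≈ 0.38 < 1
        sim = simulate_growth_reactor(cfg, duration=3000.0)
        assert sim.diagnostics["washout"] == 1.0
        assert sim.steady_state["biomass"] == 0.0
        assert sim["biomass"][-1] < 1e3


class TestReductionReactor:
    INLET = {"fe3": 0.0, "fe2": 1200.0, "biomass": 4e9}

    def test_zero_rate_mixing_formula(self):
        cfg = ReductionReactorConfig(rate_law=RateLaw(0.0, 0.0))
        ss = steady_state(cfg, self.INLET)
        q1, q2 = cfg.pulp_inflow, cfg.feed_flow
        expected = (q1 * 1200.0 + q2 * 22000.0) / (q1 + q2)
        assert ss["fe_total"] == pytest.approx(expected, rel=1e-12)

    def test_biomass_is_conservative_tracer(self):
        cfg = ReductionReactorConfig()
        ss = steady_state(cfg, self.INLET)
        assert ss["biomass"] == pytest.approx(
            4e9 * cfg.pulp_inflow / cfg.outflow, rel=1e-12
        )

    def test_closed_form_matches_transient(self):
        cfg = ReductionReactorConfig()
        ss = steady_state(cfg, self.INLET)
        sim = simulate_reduction_reactor(cfg, self.INLET, duration=12000.0, step=200.0)
        for key in ("fe3", "fe2", "biomass"):
            assert sim[key][-1] == pytest.approx(ss[key], rel=1e-6)

    def test_closed_form_matches_transient_on_clipped_branch(self):
        # a steep law exhausts the Fe(III) feed: the τ_clip branch governs
        cfg = ReductionReactorConfig(rate_law=RateLaw(2e-8, 5.0))
        ss = steady_state(cfg, self.INLET)
        sim = simulate_reduction_reactor(cfg, self.INLET, duration=12000.0, step=200.0)
        assert ss["fe3"] == pytest.approx(ss["rate"] * cfg.tau_clip, rel=1e-9)
        for key in ("fe3", "fe2"):
            assert sim[key][-1] == pytest.approx(ss[key], rel=1e-5, abs=1e-6)

    def test_transient_iron_balance(self):
        cfg = ReductionReactorConfig(k_precip=2e-3)
        sim = simulate_reduction_reactor(cfg, self.INLET, duration=5000.0, step=100.0)
        assert sim.diagnostics["iron_balance"] < 1e-9

    def test_zero_feed_gives_zero_state(self):
        cfg = ReductionReactorConfig(fe3_feed=0.0, rate_law=RateLaw(0.0, 0.0))
        ss = steady_state(cfg, {"fe3": 0.0, "fe2": 0.0, "biomass": 0.0})
        assert ss["fe3"] == ss["fe2"] == ss["biomass"] == 0.0

    def test_steady_rate_closes_the_fe2_balance(self):
        cfg = ReductionReactorConfig()
        ss = steady_state(cfg, self.INLET)
        v = volumetric_reduction_rate(ss["fe2"], 1200.0, cfg.outflow,
                                      cfg.pulp_inflow, cfg.volume)
        assert v == pytest.approx(ss["rate"], rel=1e-9)


class TestVolumetricRate:
    def test_equal_in_out_is_zero(self):
        assert volumetric_reduction_rate(800.0, 800.0, 26.5, 26.5, 4.0) == 0.0

    def test_volume_scaling(self):
        r4 = volumetric_reduction_rate(1800.0, 100.0, 29.5, 26.5, 4.0)
        r8 = volumetric_reduction_rate(1800.0, 100.0, 29.5, 26.5, 8.0)
        assert r4 == pytest.approx(2.0 * r8, rel=1e-12)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            volumetric_reduction_rate(1.0, 0.0, 1.0, 1.0, 0.0)


class TestCascade:
    def test_fe3_fraction_decreases_with_biomass_and_slope(self):
        base_growth = GrowthReactorConfig()
        red = ReductionReactorConfig()
        _, r2_base = simulate_cascade(base_growth, red, duration=3000.0, step=50.0)
        # more biomass (higher carrying capacity) → more reduction
        rich = GrowthReactorConfig(carrying_capacity=5.8e9)
        _, r2_rich = simulate_cascade(rich, red, duration=3000.0, step=50.0)
        assert (r2_rich.steady_state["fe3_fraction"]
                < r2_base.steady_state["fe3_fraction"])
        # steeper rate law → more reduction
        steep = ReductionReactorConfig(rate_law=RateLaw(6e-9, 1.55))
        _, r2_steep = simulate_cascade(base_growth, steep, duration=3000.0, step=50.0)
        assert (r2_steep.steady_state["fe3_fraction"]
                < r2_base.steady_state["fe3_fraction"])

    def test_default_cascade_reaches_stage1_like_state(self):
        # stage-1-like settings: ~2e9 cells·mL⁻¹ upstream, ≈53 % Fe(III)
        r1, r2 = simulate_cascade(GrowthReactorConfig(), ReductionReactorConfig(),
                                  duration=4000.0, step=50.0)
        assert r1.steady_state["biomass"] == pytest.approx(2e9, rel=0.05)
        assert r2.steady_state["fe3_fraction"] == pytest.approx(0.53, abs=0.05)
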