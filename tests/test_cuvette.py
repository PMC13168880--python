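"""Steady-state chamber solvers: closed-form oracles, mass-balance closure,
and the qualitative response shapes of the coupled system."""

import numpy as np
import pytest

import leafcos as lc
from leafcos.cuvette import RATIO_B_CO2, RATIO_B_COS, RATIO_S_CO2, RATIO_S_COS
from leafcos.kinetics import CAKinetics, GammaCosSpec, RubiscoKinetics
from dataclasses import replace

from conftest import closure_residuals


class TestWetDryConversion:
    def test_hand_value(self):
        assert lc.wet_to_dry(950.0, 20.0) == pytest.approx(950.0 / 0.98, rel=1e-12)

    def test_dry_air_identity(self):
        assert lc.wet_to_dry(123.0, 0.0) == 123.0
        assert lc.dry_to_wet(123.0, 0.0) == 123.0

    def test_round_trip(self):
        x = np.linspace(1.0, 2000.0, 50)
        h = np.linspace(0.0, 60.0, 50)
        assert np.allclose(lc.dry_to_wet(lc.wet_to_dry(x, h), h), x, rtol=1e-14)

    def test_saturated_air_rejected(self):
        with pytest.raises(ValueError):
            lc.wet_to_dry(1.0, 1000.0)


class TestH2OSolve:
    def test_canonical_condition_against_series_oracle(self, chamber, posterior_leaf):
        """Independent series-conductance solution of the linear chain."""
        sol = lc.solve_h2o(chamber, posterior_leaf, 15.0, 25.0, g_sw=0.6)
        # oracle: total conductance of q, g_bw, g_sw, g_mw in series
        q = chamber.af / chamber.s
        x_c = 1000.0 * 613.5 * np.exp(17.502 * 25 / (25 + 240.97)) / chamber.p_air
        g_tot = 1.0 / (1.0 / q + 1.0 / 2.44 + 1.0 / 0.6 + 1.0 / 10.0)
        f = g_tot * (15.0 - x_c)
        assert sol.x_a == pytest.approx(15.0 - f / q, rel=1e-12)
        assert sol.x_a == pytest.approx(23.57, abs=0.01)
        assert sol.e_h2o == pytest.approx(3.33e-3, abs=2e-5)
        assert sol.rh_i == pytest.approx(98.9, abs=0.05)
        assert sol.rh_i <= 100.0

    def test_infinite_mesophyll_conductance_saturates_airspace(self, chamber, posterior_leaf):
        leaf = replace(posterior_leaf, g_mw=1e9)
        sol = lc.solve_h2o(chamber, leaf, 15.0, 25.0)
        assert sol.rh_i == pytest.approx(100.0, abs=1e-6)

    def test_equilibrium_at_saturation(self, chamber, posterior_leaf):
        x_c = lc.kinetics.h2o_saturated_mole_fraction(25.0, chamber.p_air)
        sol = lc.solve_h2o(chamber, posterior_leaf, x_c, 25.0)
        assert sol.f_gas == pytest.approx(0.0, abs=1e-12)
        for layer in (sol.x_a, sol.x_b, sol.x_i):
            assert layer == pytest.approx(x_c, rel=1e-12)

    def test_supersaturated_inflow_rejected(self, chamber, posterior_leaf):
        with pytest.raises(ValueError):
            lc.solve_h2o(chamber, posterior_leaf, 40.0, 25.0)


class TestCOSSolve:
    def test_uniform_equilibrium_at_gamma(self, chamber, posterior_leaf):
        gamma = lc.gamma_cos(25.0, posterior_leaf.gamma)
        sol = lc.solve_cos(chamber, posterior_leaf, gamma, 25.0, e_h2o=0.0)
        assert sol.f_gas == pytest.approx(0.0, abs=1e-10)
        for layer in (sol.x_a, sol.x_b, sol.x_i):
            assert layer == pytest.approx(gamma, rel=1e-12)

    def test_three_resistor_series_oracle(self, chamber):
        """With no ternary term the chain is four resistors in series; the
        closed-form network solution is an independent oracle."""
        leaf = lc.LeafParameters(g_sw=0.5, gamma=GammaCosSpec.s1(),
                                 ca=CAKinetics(v_max_ca=0.2, t_eq_ca=30.0))
        t = 25.0
        sol = lc.solve_cos(chamber, leaf, 800.0, t, e_h2o=0.0)
        q = chamber.af / chamber.s
        g_b, g_s = chamber.g_bw / RATIO_B_COS, 0.5 / RATIO_S_COS
        g_m = lc.g_m_cos(t, leaf.ca)
        g_tot = 1.0 / (1.0 / q + 1.0 / g_b + 1.0 / g_s + 1.0 / g_m)
        f = g_tot * 800.0
        assert sol.f_gas == pytest.approx(f, rel=1e-10)
        assert sol.x_i == pytest.approx(800.0 - f * (1/q + 1/g_b + 1/g_s), rel=1e-10)

    def test_two_resistor_limit_large_gm(self, chamber):
        """g_m -> infinity pins the intercellular level at the mesophyll
        value; x_i follows the two-conductance divider."""
        leaf = lc.LeafParameters(g_sw=0.5, gamma=GammaCosSpec.s1(),
                                 ca=CAKinetics(v_max_ca=1e9, t_eq_ca=30.0))
        sol = lc.solve_cos(chamber, leaf, 800.0, 30.0, e_h2o=0.0)
        assert sol.x_i == pytest.approx(0.0, abs=1e-4)

    def test_flux_linear_in_inflow(self, chamber, posterior_leaf):
        xs = np.array([300.0, 700.0, 1100.0])
        f = np.array([lc.solve_cos(chamber, posterior_leaf, x, 25.0, 3e-3).f_gas
                      for x in xs])
        slope1 = (f[1] - f[0]) / (xs[1] - xs[0])
        slope2 = (f[2] - f[1]) / (xs[2] - xs[1])
        assert slope1 == pytest.approx(slope2, rel=1e-10)

    def test_singular_system_rejected(self, chamber, posterior_leaf):
        with pytest.raises(ValueError):
            lc.solve_cos(chamber, posterior_leaf, 800.0, 25.0, 0.0, g_sw=0.0)


class TestCO2Solve:
    def test_respiration_only_is_a_source(self, chamber, posterior_leaf):
        leaf = replace(posterior_leaf, rub=RubiscoKinetics(v_max_rub=0.0))
        sol = lc.solve_co2(chamber, leaf, 400.0, 25.0, e_h2o=0.0)
        assert sol.f_gas == pytest.approx(-leaf.co2c.rd(25.0), rel=1e-9)
        assert sol.x_a > 400.0

    def test_grid_oracle(self, chamber, posterior_leaf):
        """Brute-force supply-demand crossing on a dense grid."""
        t, x_in, e = 27.0, 420.0, 3e-3
        sol = lc.solve_co2(chamber, posterior_leaf, x_in, t, e)
        q = chamber.af / chamber.s
        g_b, g_s = chamber.g_bw / RATIO_B_CO2, posterior_leaf.g_sw / RATIO_S_CO2
        beta = 1/q + 1/g_b
        alpha = (g_s - e/2) / (g_s + e/2)
        k = alpha * beta + 1.0 / (g_s + e/2)
        grid = np.linspace(1e-3, 2 * x_in, 10_000)
        supply = (alpha * x_in - grid) / k
        demand = lc.rubisco_assimilation(grid * chamber.p_air * 1e-6, t,
                                         posterior_leaf.rub, posterior_leaf.co2c) \
            - posterior_leaf.co2c.rd(t)
        x_grid = grid[np.argmin(np.abs(supply - demand))]
        assert sol.x_i == pytest.approx(x_grid, abs=2 * (grid[1] - grid[0]))

    def test_zero_flux_at_compensation_without_respiration(self, chamber, posterior_leaf):
        c = replace(posterior_leaf.co2c, rd_298=0.0)
        leaf = replace(posterior_leaf, co2c=c)
        g_star = lc.gamma_star_co2(25.0, c)
        x_comp = g_star / (chamber.p_air * 1e-6)  # umol/mol at which A_m = 0
        sol = lc.solve_co2(chamber, leaf, x_comp, 25.0, e_h2o=0.0)
        assert sol.f_gas == pytest.approx(0.0, abs=1e-10)
        assert sol.x_i == pytest.approx(x_comp, rel=1e-10)


class TestFluxDiagnostics:
    def test_net_flux_arithmetic(self, chamber):
        assert lc.net_flux(chamber, 600.0, 500.0) == pytest.approx(
            3.5e-4 / 9e-4 * 100.0, rel=1e-12)
        assert lc.net_flux(chamber, 500.0, 500.0) == 0.0
        assert lc.net_flux(chamber, 500.0, 600.0) == -lc.net_flux(chamber, 600.0, 500.0)

    def test_deposition_velocity_limits(self):
        g_bs = 1.0 / (1.0 / 1.5 + 1.0 / 0.3)
        assert lc.deposition_velocity(500.0, 0.0, 1.5, 0.3) == pytest.approx(g_bs)
        assert lc.deposition_velocity(500.0, 500.0, 1.5, 0.3) == 0.0
        assert lc.afr(500.0, 0.0) == 1.0
        assert lc.afr(100.0, 63.0) == pytest.approx(0.37, rel=1e-12)
        with pytest.raises(ZeroDivisionError):
            lc.afr(0.0, 1.0)

    def test_lru_arithmetic(self):
        assert lc.lru(30.0, 1000.0, 15.0, 400.0) == pytest.approx(0.8, rel=1e-12)
        assert lc.lru(5.0, 100.0, 5.0, 100.0) == 1.0
        assert lc.lru(0.0, 100.0, 5.0, 100.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            lc.lru(1.0, 100.0, 0.0, 100.0)


class TestForwardSimulate:
    def test_canonical_condition_runs_with_uptake(self, chamber, posterior_leaf):
        sim = lc.forward_simulate(chamber, posterior_leaf, 1000.0, 400.0, 15.0, 25.0)
        assert sim.f_cos > 0 and sim.f_co2 > 0
        assert sim.cos_out_dry < 1000.0 and sim.co2_out_dry < 400.0

    def test_inert_leaf_passes_gas_through(self, chamber, posterior_leaf):
        # at saturation inflow there is no transpiration, so wet and dry
        # bases coincide and an inert leaf leaves both gases untouched
        leaf = replace(posterior_leaf,
                       ca=CAKinetics(v_max_ca=0.0, t_eq_ca=30.0),
                       rub=RubiscoKinetics(v_max_rub=0.0),
                       co2c=replace(posterior_leaf.co2c, rd_298=0.0))
        h_sat = lc.kinetics.h2o_saturated_mole_fraction(25.0, chamber.p_air)
        sim = lc.forward_simulate(chamber, leaf, 1000.0, 400.0, h_sat, 25.0)
        assert sim.f_cos == pytest.approx(0.0, abs=1e-9)
        assert sim.f_co2 == pytest.approx(0.0, abs=1e-9)
        assert sim.cos_out_dry == pytest.approx(lc.wet_to_dry(
            lc.dry_to_wet(1000.0, h_sat), h_sat), rel=1e-12)
        # with transpiration the wet-basis ambient still equals the inflow
        sim_wet = lc.forward_simulate(chamber, leaf, 1000.0, 400.0, 15.0, 25.0)
        assert sim_wet.cos.x_a == pytest.approx(lc.dry_to_wet(1000.0, 15.0), rel=1e-12)
        # respiration alone makes CO2 a source
        leaf_rd = replace(leaf, co2c=posterior_leaf.co2c)
        sim_rd = lc.forward_simulate(chamber, leaf_rd, 1000.0, 400.0, h_sat, 25.0)
        assert sim_rd.co2_out_dry > 400.0

    def test_flux_equals_mesophyll_sink(self, chamber, posterior_leaf):
        """Linearity chain closure: the chamber-balance COS flux equals the
        mesophyll uptake term."""
        sim = lc.forward_simulate(chamber, posterior_leaf, 1000.0, 400.0, 15.0, 25.0)
        g_m = lc.g_m_cos(25.0, posterior_leaf.ca)
        sink = g_m * (sim.cos.x_i - lc.gamma_cos(25.0, posterior_leaf.gamma))
        assert sim.cos.f_gas == pytest.approx(sink, rel=1e-9)


@pytest.mark.parametrize("t_leaf,x_cos,x_co2,g_sw", [
    (19.0, 300.0, 380.0, 0.3),
    (25.0, 1000.0, 445.0, 0.6),
    (30.9, 1100.0, 445.0, 1.1),
])
def test_mass_balance_closure_all_gases(chamber, posterior_leaf, t_leaf, x_cos,
                                        x_co2, g_sw):
    """Every solved gas satisfies all three chained balance equations to
    1e-9 relative."""
    sim = lc.forward_simulate(chamber, posterior_leaf, x_cos, x_co2, 15.0,
                              t_leaf, g_sw=g_sw)
    g_b_cos, g_s_cos = chamber.g_bw / RATIO_B_COS, g_sw / RATIO_S_COS
    g_b_co2, g_s_co2 = chamber.g_bw / RATIO_B_CO2, g_sw / RATIO_S_CO2
    g_m = lc.g_m_cos(t_leaf, posterior_leaf.ca)
    sink_cos = g_m * (sim.cos.x_i - lc.gamma_cos(t_leaf, posterior_leaf.gamma))
    res = closure_residuals(chamber, sim.cos, g_b_cos, g_s_cos, sink_cos)
    assert np.max(np.abs(res)) < 1e-9
    sink_co2 = lc.rubisco_assimilation(sim.co2.x_i * chamber.p_air * 1e-6, t_leaf,
                                       posterior_leaf.rub, posterior_leaf.co2c) \
        - posterior_leaf.co2c.rd(t_leaf)
    res = closure_residuals(chamber, sim.co2, g_b_co2, g_s_co2, sink_co2)
    assert np.max(np.abs(res)) < 1e-9
    # H2O: same chain without ternary term, mesophyll source at saturation
    h = sim.h2o
    sink_h2o = posterior_leaf.g_mw * (h.x_i - h.x_c)
    terms = np.array([
        chamber.q * (np.asarray(h.x_in) - h.x_a),
        chamber.g_bw * (h.x_a - h.x_b),
        g_sw * (h.x_b - h.x_i),
        sink_h2o,
    ])
    assert np.max(np.abs(terms - terms[0])) / np.max(np.abs(terms)) < 1e-9


def test_steady_state_independent_of_reservoir_volumes(posterior_leaf):
    """The accumulation terms vanish at steady state, so cuvette volume and
    molar volume must not affect any result."""
    a = lc.ChamberConfig()
    b = lc.ChamberConfig(v_cv=a.v_cv * 10, v_m=a.v_m * 10)
    sa = lc.forward_simulate(a, posterior_leaf, 1000.0, 400.0, 15.0, 25.0)
    sb = lc.forward_simulate(b, posterior_leaf, 1000.0, 400.0, 15.0, 25.0)
    assert sa.cos_out_dry == sb.cos_out_dry
    assert sa.co2_out_dry == sb.co2_out_dry
    assert sa.h2o_out == sb.h2o_out


def test_deposition_velocity_monotonicity(chamber, posterior_leaf):
    """V_COS rises with stomatal opening and falls with the compensation
    point."""
    g_sw = np.linspace(0.2, 1.2, 12)
    sim = lc.forward_simulate(chamber, posterior_leaf, 1000.0, 400.0, 15.0, 25.0,
                              g_sw=g_sw)
    assert np.all(np.diff(sim.diagnostics.v_cos) > 0)
    v = []
    for m_cos in (5.0, 15.0, 25.0, 35.0):
        leaf = replace(posterior_leaf, gamma=GammaCosSpec.s2(m_cos=m_cos))
        v.append(lc.forward_simulate(chamber, leaf, 1000.0, 400.0, 15.0,
                                     25.0).diagnostics.v_cos)
    assert np.all(np.diff(v) < 0)


def test_lru_increases_and_saturates_with_gsw(chamber, posterior_leaf):
    """LRU rises with g_sw and flattens: the relative increments shrink."""
    g_sw = np.linspace(0.2, 1.2, 21)
    sim = lc.forward_simulate(chamber, posterior_leaf, 1000.0, 445.0, 15.0, 25.0,
                              g_sw=g_sw)
    lru = np.asarray(sim.diagnostics.lru)
    assert np.all(np.diff(lru) >= 0)
    assert np.diff(lru)[-1] < 0.25 * np.diff(lru)[0]
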