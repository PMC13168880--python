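"""Analytic steady state of the leaf-cuvette system for COS, CO2 and H2O.

The chamber balance chains four well-mixed layers: ambient cuvette air (a),
leaf boundary layer (b), intercellular airspace (i) and mesophyll surface
(c).  Flushing (AF/S), boundary, stomatal and mesophyll conductances connect
them in series; for the trace gases the stomatal step carries a ternary
correction for the bulk outflow of transpired water.  At steady state the
accumulation terms vanish, so the cuvette volume and molar volume never
enter the solution and each gas reduces to a small algebraic system:

* H2O - linear series chain from the saturated mesophyll down to the inflow;
* COS - linear 3x3 system with the mesophyll sink g_m,COS (x_i - Gamma_COS),
  solved in closed form;
* CO2 - the mesophyll sink is the nonlinear A_m(p_i) - R_d, leaving one
  scalar root in x_i which is bracketed and bisected.

All solvers are vectorized: scalar or broadcastable array inputs are both
accepted, which is what makes the surrounding state inversion affordable.
Mole fractions are wet-air basis internally (pmol/umol/mmol per mol for
COS/CO2/H2O); dry-air conversion happens only at the measurement boundary.
Fluxes are uptake-positive; transpiration ``e`` is a separate
outward-positive quantity in mol m-2 s-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinetics import (
    CAKinetics,
    CO2Constants,
    GammaCosSpec,
    RubiscoKinetics,
    f_rub,
    g_m_cos,
    gamma_cos,
    gamma_star_co2,
    h2o_saturated_mole_fraction,
)

__all__ = [
    "ChamberConfig",
    "LeafParameters",
    "SpeciesConductances",
    "SteadyStateProfile",
    "FluxDiagnostics",
    "SimulatedPoint",
    "species_conductances",
    "wet_to_dry",
    "dry_to_wet",
    "solve_h2o",
    "solve_cos",
    "solve_co2",
    "net_flux",
    "deposition_velocity",
    "afr",
    "lru",
    "forward_simulate",
]

# Diffusivity ratios of each trace gas to water vapour (stomatal, boundary).
RATIO_S_CO2 = 1.6
RATIO_B_CO2 = 1.4
RATIO_S_COS = 1.94
RATIO_B_COS = 1.56


@dataclass
class ChamberConfig:
    """Cuvette geometry and flow.

    af : air flow through the cuvette (mol s-1).
    s : enclosed leaf area (m2).
    p_air : cuvette air pressure (Pa).
    g_bw : boundary-layer conductance for H2O (mol m-2 s-1), set by the
        mixing fan.
    v_cv, v_m : cuvette volume (m3) and molar volume (m3 mol-1).  They scale
        the accumulation terms only and drop out of every steady-state
        result; they are kept so transient extensions stay expressible.
    """

    af: float | np.ndarray = 3.5e-4
    s: float | np.ndarray = 9e-4
    p_air: float | np.ndarray = 103_100.0
    g_bw: float | np.ndarray = 2.44
    v_cv: float = 109e-6
    v_m: float = 0.0248

    def __post_init__(self):
        for name in ("af", "s", "p_air", "g_bw", "v_cv", "v_m"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")

    @property
    def q(self) -> float | np.ndarray:
        """Flushing conductance AF/S (mol m-2 s-1)."""
        return self.af / self.s


@dataclass
class LeafParameters:
    """Full physiological state of one leaf.

    g_sw : stomatal conductance for H2O (mol m-2 s-1); may be an array when
        solving many data points at once.
    g_mw : mesophyll conductance for H2O (mol m-2 s-1); large by default so
        the intercellular airspace sits close to saturation.
    ca, rub, co2c, gamma : kinetics parameter containers.
    """

    g_sw: float | np.ndarray = 0.6
    g_mw: float = 10.0
    ca: CAKinetics = field(default_factory=CAKinetics)
    rub: RubiscoKinetics = field(default_factory=RubiscoKinetics)
    co2c: CO2Constants = field(default_factory=CO2Constants)
    gamma: GammaCosSpec = field(default_factory=GammaCosSpec)


@dataclass
class SpeciesConductances:
    """Stomatal and boundary conductances per gas, scaled from water vapour
    by fixed binary diffusivity ratios."""

    g_s_cos: float | np.ndarray
    g_b_cos: float | np.ndarray
    g_s_co2: float | np.ndarray
    g_b_co2: float | np.ndarray
    g_sw: float | np.ndarray
    g_bw: float | np.ndarray


def species_conductances(g_sw, g_bw) -> SpeciesConductances:
    g_sw = np.asarray(g_sw, dtype=float)
    return SpeciesConductances(
        g_s_cos=g_sw / RATIO_S_COS,
        g_b_cos=g_bw / RATIO_B_COS,
        g_s_co2=g_sw / RATIO_S_CO2,
        g_b_co2=g_bw / RATIO_B_CO2,
        g_sw=g_sw,
        g_bw=g_bw,
    )


@dataclass
class SteadyStateProfile:
    """Layer mole fractions and net flux for one gas (wet-air basis).

    x_a/x_b/x_i/x_c : ambient, boundary, intercellular and mesophyll-level
    mole fractions in the gas's own per-mol unit; f_gas : net uptake flux
    (same unit m-2 s-1); e_h2o : transpiration (mol m-2 s-1, positive out).
    """

    gas: str
    x_in: float | np.ndarray
    x_a: float | np.ndarray
    x_b: float | np.ndarray
    x_i: float | np.ndarray
    x_c: float | np.ndarray
    f_gas: float | np.ndarray
    e_h2o: float | np.ndarray = 0.0
    rh_i: Optional[float | np.ndarray] = None


@dataclass
class FluxDiagnostics:
    """Derived per-point diagnostics: deposition velocities, ambient
    fraction remaining, leaf relative uptake, intercellular RH."""

    v_cos: float | np.ndarray
    v_co2: float | np.ndarray
    afr_cos: float | np.ndarray
    afr_co2: float | np.ndarray
    lru: float | np.ndarray
    rh_i: float | np.ndarray


def wet_to_dry(x_wet, h2o):
    """Convert a wet-air mole fraction to dry-air basis given the H2O mole
    fraction (mmol mol-1) of the same air."""
    h2o = np.asarray(h2o, dtype=float)
    if np.any(h2o < 0) or np.any(h2o >= 1000.0):
        raise ValueError("h2o must lie in [0, 1000) mmol mol-1")
    out = np.asarray(x_wet, dtype=float) / (1.0 - h2o / 1000.0)
    return out if out.ndim else float(out)


def dry_to_wet(x_dry, h2o):
    """Inverse of :func:`wet_to_dry`; exact round trip."""
    h2o = np.asarray(h2o, dtype=float)
    if np.any(h2o < 0) or np.any(h2o >= 1000.0):
        raise ValueError("h2o must lie in [0, 1000) mmol mol-1")
    out = np.asarray(x_dry, dtype=float) * (1.0 - h2o / 1000.0)
    return out if out.ndim else float(out)


def net_flux(cfg: ChamberConfig, x_in, x_a):
    """Chamber mass-balance flux F = (AF/S)(x_in - x_a); uptake-positive."""
    out = cfg.q * (np.asarray(x_in, dtype=float) - np.asarray(x_a, dtype=float))
    return out if out.ndim else float(out)


def solve_h2o(cfg: ChamberConfig, leaf: LeafParameters, x_in, t_leaf,
              g_sw=None) -> SteadyStateProfile:
    """Steady-state H2O profile and transpiration.

    The mesophyll surface is saturated ([H2O]_c from leaf temperature and
    pressure); the flux runs outward through g_mw, g_sw, g_bw and the
    chamber flushing in series.  ``g_sw`` may override the value in ``leaf``
    (used when sweeping per-point conductances).
    """
    g_sw_eff = np.asarray(leaf.g_sw if g_sw is None else g_sw, dtype=float)
    if np.any(g_sw_eff <= 0) or leaf.g_mw <= 0:
        raise ValueError("conductances must be positive")
    x_in = np.asarray(x_in, dtype=float)
    x_c = h2o_saturated_mole_fraction(t_leaf, cfg.p_air)
    if np.any(x_in > np.asarray(x_c) + 1e-12):
        raise ValueError("inflowing H2O exceeds saturation at leaf temperature")
    q = cfg.q
    g_tot = 1.0 / (1.0 / q + 1.0 / cfg.g_bw + 1.0 / g_sw_eff + 1.0 / leaf.g_mw)
    # Uptake-positive flux (negative here: water evaporates).
    f = g_tot * (x_in - x_c)
    x_a = x_in - f / q
    x_b = x_a - f / cfg.g_bw
    x_i = x_b - f / g_sw_eff
    rh_i = 100.0 * x_i / x_c
    return SteadyStateProfile(
        gas="h2o", x_in=x_in, x_a=x_a, x_b=x_b, x_i=x_i, x_c=x_c,
        f_gas=f, e_h2o=-f / 1000.0, rh_i=rh_i,
    )


def _ternary_coefficients(q, g_b, g_s, e):
    """Closed-form elimination of the 3-layer chain with the stomatal
    ternary term.

    With uptake-positive flux F: x_a = x_in - F/q, x_b = x_in - F beta, and
    the stomatal balance F = g_s (x_b - x_i) - e (x_b + x_i)/2 gives
    x_i = alpha x_in - F k.  Returns (alpha, beta, k).
    """
    beta = 1.0 / q + 1.0 / g_b
    den = g_s + 0.5 * e
    alpha = (g_s - 0.5 * e) / den
    k = alpha * beta + 1.0 / den
    return alpha, beta, k


def solve_cos(cfg: ChamberConfig, leaf: LeafParameters, x_in_wet, t_leaf,
              e_h2o, g_sw=None) -> SteadyStateProfile:
    """Steady-state COS profile (wet basis, pmol mol-1).

    Mesophyll sink g_m,COS(T) (x_i - Gamma_COS(T)) closes the linear chain;
    the whole system is solved in closed form, so the mass-balance residuals
    are at machine precision.
    """
    g_sw_eff = np.asarray(leaf.g_sw if g_sw is None else g_sw, dtype=float)
    g_s = g_sw_eff / RATIO_S_COS
    g_b = cfg.g_bw / RATIO_B_COS
    if np.any(g_s <= 0):
        raise ValueError("stomatal conductance must be positive")
    x_in = np.asarray(x_in_wet, dtype=float)
    e = np.asarray(e_h2o, dtype=float)
    g_m = g_m_cos(t_leaf, leaf.ca)
    gamma = gamma_cos(t_leaf, leaf.gamma)
    alpha, beta, k = _ternary_coefficients(cfg.q, g_b, g_s, e)
    f = g_m * (alpha * x_in - gamma) / (1.0 + g_m * k)
    x_a = x_in - f / cfg.q
    x_b = x_in - f * beta
    x_i = alpha * x_in - f * k
    return SteadyStateProfile(
        gas="cos", x_in=x_in, x_a=x_a, x_b=x_b, x_i=x_i, x_c=gamma,
        f_gas=f, e_h2o=e,
    )


def solve_co2(cfg: ChamberConfig, leaf: LeafParameters, x_in_wet, t_leaf,
              e_h2o, g_sw=None) -> SteadyStateProfile:
    """Steady-state CO2 profile (wet basis, umol mol-1).

    The mesophyll term is the nonlinear net biochemical sink A_m(p_i) -
    R_d(T).  Diffusive supply through the chain is linear and strictly
    decreasing in x_i while the Michaelis-Menten sink is a rational,
    strictly increasing function of x_i, so the balance reduces to a
    quadratic in x_i with exactly one positive root, taken here in its
    numerically stable closed form.  The respiration-source case (V_max,Rub
    small, outflow above inflow) falls out of the same root.
    """
    g_sw_eff = np.asarray(leaf.g_sw if g_sw is None else g_sw, dtype=float)
    g_s = g_sw_eff / RATIO_S_CO2
    g_b = cfg.g_bw / RATIO_B_CO2
    if np.any(g_s <= 0):
        raise ValueError("stomatal conductance must be positive")
    x_in = np.asarray(x_in_wet, dtype=float)
    if np.any(x_in <= 0):
        raise ValueError("inflowing CO2 must be positive")
    e = np.asarray(e_h2o, dtype=float)
    alpha, beta, k = _ternary_coefficients(cfg.q, g_b, g_s, e)
    rd = np.asarray(leaf.co2c.rd(t_leaf), dtype=float)
    p_fac = cfg.p_air * 1e-6  # umol mol-1 (wet) -> Pa
    vm = leaf.rub.v_max_rub * f_rub(t_leaf, leaf.rub)
    g_star = gamma_star_co2(t_leaf, leaf.co2c)
    k_eff = leaf.co2c.kc(t_leaf) * (1.0 + leaf.co2c.p_o2_i / leaf.co2c.ko(t_leaf))
    # Supply (alpha x_in - x_i)/k against demand vm (p x_i - G*)/(p x_i + K') - rd:
    # p x_i^2 + b x_i + c = 0 with one positive root (a > 0, c < 0).
    b = k_eff + p_fac * k * (vm - rd) - p_fac * alpha * x_in
    c = -(k_eff * alpha * x_in + k * (vm * g_star + rd * k_eff))
    disc = b * b - 4.0 * p_fac * c
    x_i = -2.0 * c / (b + np.sqrt(disc))
    f = (alpha * x_in - x_i) / k
    x_a = x_in - f / cfg.q
    x_b = x_in - f * beta
    if not np.ndim(x_i):
        x_i, f, x_a, x_b = (float(v) for v in (x_i, f, x_a, x_b))
    return SteadyStateProfile(
        gas="co2", x_in=x_in, x_a=x_a, x_b=x_b, x_i=x_i, x_c=x_i,
        f_gas=f, e_h2o=e,
    )


def deposition_velocity(x_a, x_i, g_b, g_s):
    """Deposition velocity V = g_b~s (1 - x_i/x_a), with g_b~s the series
    conductance from boundary layer to stomata."""
    x_a = np.asarray(x_a, dtype=float)
    if np.any(x_a == 0):
        raise ZeroDivisionError("ambient mole fraction must be non-zero")
    g_bs = 1.0 / (1.0 / np.asarray(g_b, float) + 1.0 / np.asarray(g_s, float))
    out = g_bs * (1.0 - np.asarray(x_i, float) / x_a)
    return out if out.ndim else float(out)


def afr(x_a, x_i):
    """Ambient fraction remaining, 1 - x_i/x_a."""
    x_a = np.asarray(x_a, dtype=float)
    if np.any(x_a == 0):
        raise ZeroDivisionError("ambient mole fraction must be non-zero")
    out = 1.0 - np.asarray(x_i, float) / x_a
    return out if out.ndim else float(out)


def lru(a_cos, cos_out, a_co2, co2_out):
    """Leaf relative uptake: COS to CO2 assimilation, each normalized by its
    outflowing mole fraction."""
    cos_out = np.asarray(cos_out, dtype=float)
    co2_out = np.asarray(co2_out, dtype=float)
    a_co2 = np.asarray(a_co2, dtype=float)
    if np.any(cos_out <= 0) or np.any(co2_out <= 0):
        raise ZeroDivisionError("outflowing mole fractions must be positive")
    if np.any(a_co2 == 0):
        raise ZeroDivisionError("CO2 assimilation must be non-zero")
    out = (np.asarray(a_cos, float) / cos_out) / (a_co2 / co2_out)
    return out if out.ndim else float(out)


@dataclass
class SimulatedPoint:
    """Forward-simulation output at one (or a vector of) steady-state
    condition(s): dry-basis outflows, fluxes and diagnostics, plus the full
    wet-basis layer profiles."""

    cos_out_dry: float | np.ndarray
    co2_out_dry: float | np.ndarray
    h2o_out: float | np.ndarray
    f_cos: float | np.ndarray
    f_co2: float | np.ndarray
    e_h2o: float | np.ndarray
    cos: SteadyStateProfile
    co2: SteadyStateProfile
    h2o: SteadyStateProfile
    diagnostics: FluxDiagnostics


def forward_simulate(cfg: ChamberConfig, leaf: LeafParameters, cos_in_dry,
                     co2_in_dry, h2o_in, t_leaf, g_sw=None,
                     h2o_out_obs=None) -> SimulatedPoint:
    """Full forward pipeline at given dry-basis inflows.

    Converts the trace-gas inflows to wet basis with the inflowing H2O,
    solves the H2O chain (supplying the transpiration for the ternary
    terms), solves COS and CO2, and converts the modeled ambient mole
    fractions back to dry basis.  By default the modeled ambient H2O stands
    in for the observed outflow humidity in that conversion; pass
    ``h2o_out_obs`` to use a measured value instead (the measurement-basis
    comparison used by the inversion).
    """
    cos_in_wet = dry_to_wet(cos_in_dry, h2o_in)
    co2_in_wet = dry_to_wet(co2_in_dry, h2o_in)
    h2o = solve_h2o(cfg, leaf, h2o_in, t_leaf, g_sw=g_sw)
    e = h2o.e_h2o
    cos = solve_cos(cfg, leaf, cos_in_wet, t_leaf, e, g_sw=g_sw)
    co2 = solve_co2(cfg, leaf, co2_in_wet, t_leaf, e, g_sw=g_sw)
    h2o_for_dry = h2o.x_a if h2o_out_obs is None else h2o_out_obs
    cos_out_dry = wet_to_dry(cos.x_a, h2o_for_dry)
    co2_out_dry = wet_to_dry(co2.x_a, h2o_for_dry)
    # Fluxes on the measurement (dry) basis, as for the observations.
    f_cos_dry = net_flux(cfg, np.asarray(cos_in_dry, float), cos_out_dry)
    f_co2_dry = net_flux(cfg, np.asarray(co2_in_dry, float), co2_out_dry)
    g_sw_eff = np.asarray(leaf.g_sw if g_sw is None else g_sw, dtype=float)
    sc_gs_cos = g_sw_eff / RATIO_S_COS
    sc_gb_cos = cfg.g_bw / RATIO_B_COS
    sc_gs_co2 = g_sw_eff / RATIO_S_CO2
    sc_gb_co2 = cfg.g_bw / RATIO_B_CO2
    # LRU is undefined (NaN) at zero CO2 assimilation rather than an error:
    # parameter sweeps legitimately pass through inert-leaf corners.
    with np.errstate(divide="ignore", invalid="ignore"):
        lru_val = (np.asarray(cos.f_gas, float) / np.asarray(cos.x_a, float)) / (
            np.asarray(co2.f_gas, float) / np.asarray(co2.x_a, float))
    diag = FluxDiagnostics(
        v_cos=deposition_velocity(cos.x_a, cos.x_i, sc_gb_cos, sc_gs_cos),
        v_co2=deposition_velocity(co2.x_a, co2.x_i, sc_gb_co2, sc_gs_co2),
        afr_cos=afr(cos.x_a, cos.x_i),
        afr_co2=afr(co2.x_a, co2.x_i),
        lru=lru_val if np.ndim(lru_val) else float(lru_val),
        rh_i=h2o.rh_i,
    )
    return SimulatedPoint(
        cos_out_dry=cos_out_dry, co2_out_dry=co2_out_dry, h2o_out=h2o.x_a,
        f_cos=f_cos_dry, f_co2=f_co2_dry, e_h2o=e,
        cos=cos, co2=co2, h2o=h2o, diagnostics=diag,
    )
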