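"""Temperature-response kinetics for the three gases.

Everything here is a pure function of leaf temperature and a small parameter
container: saturation vapour pressure for the H2O sub-model, Q10 scaling of
the RuBisCO Michaelis constants and dark respiration, the Arrhenius
activation factor of carboxylation, the carbonic-anhydrase (CA) mesophyll
conductance with high-temperature deactivation, and the four candidate
temperature functions of the COS compensation point.

Temperatures are degrees Celsius at the API surface; Arrhenius and Q10
expressions convert to Kelvin internally with T + 273.15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_GAS",
    "T_ZERO",
    "CAKinetics",
    "RubiscoKinetics",
    "CO2Constants",
    "GammaCosSpec",
    "saturation_vapor_pressure",
    "h2o_saturated_mole_fraction",
    "q10_scale",
    "f_rub",
    "g_m_cos",
    "gamma_cos",
    "gamma_star_co2",
    "rubisco_assimilation",
    "invert_arrhenius_dH",
]

#: Universal molar gas constant (J K-1 mol-1).
R_GAS = 8.314
#: Celsius -> Kelvin offset.
T_ZERO = 273.15

# Singularity of the Magnus-type saturation vapour pressure formula (degC).
_SVP_SINGULARITY = -240.97


def saturation_vapor_pressure(t_leaf):
    """Saturation vapour pressure over water (Pa) at leaf temperature (degC).

    Magnus-type formula 613.5 * exp(17.502 T / (T + 240.97)); strictly
    increasing in T above the singularity at -240.97 degC.
    """
    t_leaf = np.asarray(t_leaf, dtype=float)
    if np.any(t_leaf <= _SVP_SINGULARITY):
        raise ValueError(
            f"t_leaf must exceed the formula singularity at {_SVP_SINGULARITY} degC"
        )
    out = 613.5 * np.exp(17.502 * t_leaf / (t_leaf + 240.97))
    return out if out.ndim else float(out)


def h2o_saturated_mole_fraction(t_leaf, p_air):
    """Saturated H2O mole fraction (mmol mol-1) at t_leaf (degC), p_air (Pa)."""
    p_h2o = saturation_vapor_pressure(t_leaf)
    p_air = np.asarray(p_air, dtype=float)
    if np.any(p_air <= p_h2o):
        raise ValueError("air pressure must exceed the saturation vapour pressure")
    out = 1000.0 * p_h2o / p_air
    return out if np.ndim(out) else float(out)


def q10_scale(value_ref, q10, t2, t1=25.0):
    """Scale a rate from temperature t1 to t2 (degC) with a Q10 factor."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return value_ref * q10 ** ((np.asarray(t2, dtype=float) - t1) / 10.0)


@dataclass
class RubiscoKinetics:
    """Maximum carboxylation capacity and its Arrhenius temperature response.

    v_max_rub : umol m-2 s-1, carboxylation capacity at the reference
        temperature.
    dH_a_rub : J mol-1, activation energy (default 60 kJ mol-1).
    t_ref_rub : K, reference temperature (298 K; the activation factor is
        exactly 1 there).
    """

    v_max_rub: float | np.ndarray = 90.0
    dH_a_rub: float = 60_000.0
    t_ref_rub: float = 298.0

    def __post_init__(self):
        if np.any(np.asarray(self.v_max_rub) < 0):
            raise ValueError("v_max_rub must be non-negative")


def f_rub(t_leaf, kin: RubiscoKinetics):
    """Arrhenius activation factor of RuBisCO carboxylation (dimensionless).

    exp(((T_K - T_ref) dH_a) / (T_ref R T_K)); equals 1 at T_K = T_ref and is
    strictly increasing in T for positive activation energy.
    """
    t_k = np.asarray(t_leaf, dtype=float) + T_ZERO
    out = np.exp((t_k - kin.t_ref_rub) * kin.dH_a_rub / (kin.t_ref_rub * R_GAS * t_k))
    return out if out.ndim else float(out)


def _f_ca_unnormalized(t_k, dH_a, dH_eq, t_eq_k):
    num = t_k * np.exp(-dH_a / (R_GAS * t_k))
    den = 1.0 + np.exp(-dH_eq / R_GAS * (1.0 / t_k - 1.0 / t_eq_k))
    return num / den


@dataclass
class CAKinetics:
    """Carbonic-anhydrase capacity and its peaked temperature response.

    The CA-based mesophyll conductance for COS rises with an Arrhenius term
    (activation energy ``dH_a_ca``) and falls past the optimum through an
    activation->inactivation equilibrium (enthalpy ``dH_eq_ca``).  ``a_t``
    normalizes the shape so g_m,COS(t_eq_ca) = v_max_ca exactly; it is
    derived, never set by hand.

    v_max_ca : mol m-2 s-1; dH_a_ca, dH_eq_ca : J mol-1; t_eq_ca : degC.
    """

    v_max_ca: float | np.ndarray = 0.125
    t_eq_ca: float | np.ndarray = 30.0
    dH_a_ca: float = 40_000.0
    dH_eq_ca: float = 100_000.0
    a_t: float | np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if np.any(np.asarray(self.v_max_ca) < 0):
            raise ValueError("v_max_ca must be non-negative")
        t_eq = np.asarray(self.t_eq_ca)
        if np.any(t_eq < 1.0) or np.any(t_eq > 60.0):
            raise ValueError("t_eq_ca outside the admissible range [1, 60] degC")
        self.a_t = 1.0 / _f_ca_unnormalized(
            t_eq + T_ZERO, self.dH_a_ca, self.dH_eq_ca, t_eq + T_ZERO
        )


def g_m_cos(t_leaf, kin: CAKinetics):
    """CA-based mesophyll conductance for COS (mol m-2 s-1) at t_leaf (degC).

    V_max,CA * A_T * T_K * exp(-dH_a/(R T_K)) / (1 + exp(-dH_eq/R (1/T_K -
    1/T_eq_K))), Kelvin throughout.  Returns V_max,CA exactly at the optimum
    temperature by the A_T normalization.
    """
    t_k = np.asarray(t_leaf, dtype=float) + T_ZERO
    out = kin.v_max_ca * kin.a_t * _f_ca_unnormalized(
        t_k, kin.dH_a_ca, kin.dH_eq_ca, kin.t_eq_ca + T_ZERO
    )
    return out if out.ndim else float(out)


@dataclass
class CO2Constants:
    """Mesophyll CO2 biochemistry constants (values at 298 K) and Q10s.

    tau_298 : RuBisCO CO2/O2 specificity factor (dimensionless).
    kc_298, ko_298 : Michaelis constants for carboxylation/oxygenation (Pa).
    rd_298 : dark respiration (umol m-2 s-1).
    p_o2_i : intercellular O2 partial pressure (Pa).
    """

    tau_298: float = 2600.0
    q10_tau: float = 0.57
    kc_298: float = 30.0
    q10_kc: float = 2.1
    ko_298: float = 30_000.0
    q10_ko: float = 1.2
    rd_298: float = 3.0
    q10_rd: float = 2.0
    p_o2_i: float = 20_900.0

    def __post_init__(self):
        for name in ("tau_298", "kc_298", "ko_298", "p_o2_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rd_298 < 0:
            raise ValueError("rd_298 must be non-negative")

    def kc(self, t_leaf):
        return q10_scale(self.kc_298, self.q10_kc, t_leaf)

    def ko(self, t_leaf):
        return q10_scale(self.ko_298, self.q10_ko, t_leaf)

    def rd(self, t_leaf):
        return q10_scale(self.rd_298, self.q10_rd, t_leaf)

    def tau(self, t_leaf):
        return q10_scale(self.tau_298, self.q10_tau, t_leaf)


def gamma_star_co2(t_leaf, consts: CO2Constants):
    """Photorespiratory CO2 compensation point Gamma* (Pa).

    Gamma* = p[O2]_i / (2 tau(T)) with the specificity factor tau Q10-scaled
    from 298 K (Q10 = 0.57, i.e. specificity falls with warming).
    """
    return consts.p_o2_i / (2.0 * consts.tau(t_leaf))


def rubisco_assimilation(p_co2_i, t_leaf, kin: RubiscoKinetics, consts: CO2Constants):
    """Enzyme-limited gross assimilation A_m (umol m-2 s-1).

    A_m = V_max,Rub f_Rub(T) (p_i - Gamma*) / (p_i + K_c(T) (1 + p[O2]_i /
    K_o(T))).  Strictly increasing in the intercellular CO2 partial pressure
    p_i (Pa) and zero at p_i = Gamma*.
    """
    p_i = np.asarray(p_co2_i, dtype=float)
    vm = kin.v_max_rub * f_rub(t_leaf, kin)
    num = p_i - gamma_star_co2(t_leaf, consts)
    den = p_i + consts.kc(t_leaf) * (1.0 + consts.p_o2_i / consts.ko(t_leaf))
    out = vm * num / den
    return out if out.ndim else float(out)


_GAMMA_VARIANTS = ("S1", "S2", "S3", "S4")


@dataclass
class GammaCosSpec:
    """One of the four candidate temperature functions of the COS
    compensation point.

    S1: no compensation point (identically zero).
    S2: linear, m_cos * (T - t_ref_gamma), clamped at zero below the
        intercept temperature.
    S3/S4: Arrhenius around an anchor (gamma_ref at t_ref_arrh Kelvin) with
        activation energy dH_a_gamma; the two variants differ only in which
        measured anchor they start from.
    """

    variant: str = "S2"
    m_cos: float = 16.2
    t_ref_gamma: float = 16.4
    gamma_ref: float = 55.0
    t_ref_arrh: float = 293.0
    dH_a_gamma: float = 134_300.0

    def __post_init__(self):
        if self.variant not in _GAMMA_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {_GAMMA_VARIANTS}")

    @classmethod
    def s1(cls):
        return cls(variant="S1")

    @classmethod
    def s2(cls, m_cos=16.2, t_ref_gamma=16.4):
        return cls(variant="S2", m_cos=m_cos, t_ref_gamma=t_ref_gamma)

    @classmethod
    def s3(cls, dH_a_gamma=134_300.0):
        return cls(variant="S3", gamma_ref=55.0, t_ref_arrh=293.0, dH_a_gamma=dH_a_gamma)

    @classmethod
    def s4(cls, dH_a_gamma=134_300.0):
        return cls(variant="S4", gamma_ref=138.7, t_ref_arrh=298.0, dH_a_gamma=dH_a_gamma)


def gamma_cos(t_leaf, spec: GammaCosSpec):
    """COS compensation point Gamma_COS (pmol mol-1) at t_leaf (degC).

    All variants are clamped at zero from below: a compensation point is a
    mole fraction.
    """
    t = np.asarray(t_leaf, dtype=float)
    if spec.variant == "S1":
        out = np.zeros_like(t)
    elif spec.variant == "S2":
        out = spec.m_cos * (t - spec.t_ref_gamma)
    else:
        t_k = t + T_ZERO
        out = spec.gamma_ref * np.exp(
            (t_k - spec.t_ref_arrh) * spec.dH_a_gamma / (spec.t_ref_arrh * R_GAS * t_k)
        )
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def invert_arrhenius_dH(point1, point2):
    """Activation energy (J mol-1) through two (T [K], Gamma [pmol mol-1])
    anchors of the Arrhenius compensation-point form.

    dH = ln(Gamma2/Gamma1) R T1 T2 / (T2 - T1).  Feeding the result back into
    the Arrhenius form at T2 starting from (T1, Gamma1) reproduces Gamma2.
    The anchor temperatures are taken exactly as given (no Celsius offset is
    applied here).
    """
    t1, g1 = point1
    t2, g2 = point2
    if g1 <= 0 or g2 <= 0:
        raise ValueError("both compensation points must be positive")
    if t1 == t2:
        raise ValueError("anchor temperatures must differ")
    return math.log(g2 / g1) * R_GAS * t1 * t2 / (t2 - t1)
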