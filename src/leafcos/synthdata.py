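"""Synthetic cuvette datasets with the statistical structure of the three
experiment designs.

The generator runs the forward model at prescribed control levels and
overlays the measurement artifacts of a real cuvette campaign: Gaussian
observation noise per gas, a temperature-dependent COS emission from the
chamber material (which masks part of the leaf uptake and must be corrected
away), small measurement error on the reported stomatal conductance, and
plant-to-plant spread of the enzyme capacities.  Every dataset is paired
with its ground-truth record so parameter-recovery tests can close the
loop.

Designs mirror the study layout: a COS-concentration ramp at two leaf
temperatures (compensation-point detection), a stomatal-conductance sweep
near 25 degC at elevated COS, and a leaf-temperature sweep at fixed
stomatal conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import io as lio
from .cuvette import ChamberConfig, LeafParameters, forward_simulate
from .kinetics import CAKinetics, GammaCosSpec, RubiscoKinetics

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "ChamberEmissionModel",
    "default_truth",
    "generate_dataset",
    "generate_experiment_suite",
    "correct_chamber_flux",
]


@dataclass
class ExperimentDesign:
    """One controlled sweep: which variable is ramped, at which levels, and
    the constant chamber/leaf settings around it."""

    kind: str  # cos_ramp | gsw_sweep | temp_sweep
    levels: np.ndarray
    plant_id: str = "sunflower1"
    constants: dict = field(default_factory=dict)

    _KINDS = ("cos_ramp", "gsw_sweep", "temp_sweep")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        self.levels = np.asarray(self.levels, dtype=float)
        defaults = {
            "p_air_Pa": 103_100.0, "af_mol_s": 3.5e-4, "s_m2": 9e-4,
            "g_bw": 2.44, "h2o_in": 15.0, "co2_in_dry": 445.0,
        }
        if self.kind == "cos_ramp":
            defaults.update({"t_leaf_C": 25.0, "g_sw": 0.9})
        elif self.kind == "gsw_sweep":
            defaults.update({"t_leaf_C": 25.0, "cos_in_dry": 1000.0})
        else:
            defaults.update({"g_sw": 0.6, "cos_in_dry": 1000.0})
        defaults.update(self.constants)
        self.constants = defaults

    @classmethod
    def cos_ramp(cls, t_leaf: float, plant_id: str = "sunflower1",
                 levels=None, g_sw: float = 0.9, **constants):
        """Concentration-ramp design: inflowing COS stepped over roughly
        90-710 pmol mol-1 at fixed temperature."""
        levels = np.linspace(94.0, 707.0, 4) if levels is None else levels
        return cls("cos_ramp", levels, plant_id,
                   {"t_leaf_C": t_leaf, "g_sw": g_sw, **constants})

    @classmethod
    def gsw_sweep(cls, plant_id: str, levels=None, cos_in_dry: float = 1000.0,
                  **constants):
        """Stomatal sweep at ~25 degC: g_sw levels within 0.3-1.1."""
        levels = np.linspace(0.3, 1.1, 8) if levels is None else levels
        return cls("gsw_sweep", levels, plant_id,
                   {"cos_in_dry": cos_in_dry, **constants})

    @classmethod
    def temp_sweep(cls, plant_id: str, levels=None, g_sw: float = 0.6,
                   **constants):
        """Temperature sweep at fixed g_sw: T_leaf within 19-31 degC."""
        levels = np.linspace(19.0, 30.9, 12) if levels is None else levels
        return cls("temp_sweep", levels, plant_id,
                   {"g_sw": g_sw, **constants})


@dataclass
class NoiseModel:
    """Gaussian observation noise per gas (defaults: the campaign-average
    150-s standard deviations) plus the g_sw reporting error."""

    sigma_cos: float = 16.7   # pmol mol-1
    sigma_co2: float = 0.2    # umol mol-1
    sigma_h2o: float = 0.3    # mmol mol-1
    sigma_g_sw_meas: float = 0.02  # mol m-2 s-1, instrument-scale error

    def __post_init__(self):
        if min(self.sigma_cos, self.sigma_co2, self.sigma_h2o,
               self.sigma_g_sw_meas) < 0:
            raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def off(cls):
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class ChamberEmissionModel:
    """Temperature-dependent COS emission from empty-chamber material,
    linear in air temperature; it adds COS to the chamber balance and so
    masks part of the apparent leaf uptake (roughly 6-7 % at the default
    scale under typical mid-range conditions)."""

    slope: float = 0.15       # pmol m-2 s-1 per degC
    intercept: float = 0.05   # pmol m-2 s-1
    resid_sd: float = 0.0     # pmol m-2 s-1, residual scatter after the fit

    @classmethod
    def off(cls):
        return cls(0.0, 0.0, 0.0)

    def emission(self, t_air):
        """Chamber COS source flux (pmol m-2 s-1) at air temperature."""
        return np.maximum(self.intercept + self.slope * np.asarray(t_air, float), 0.0)


def default_truth(plant_id: Optional[str] = None, seed_jitter: bool = False,
                  jitter_sd: float = 0.10) -> LeafParameters:
    """Generating-truth leaf parameters: the study's posterior mean state
    (linear compensation-point variant).

    With ``seed_jitter`` the per-plant enzyme capacities get a lognormal
    jitter (sd ``jitter_sd``) deterministic in the plant id, emulating
    plant-to-plant spread.
    """
    v_ca, v_rub = 0.217, 94.4
    if plant_id is not None and seed_jitter:
        h = abs(hash_stable(plant_id)) % (2**31)
        rng = np.random.default_rng(h)
        v_ca *= float(np.exp(jitter_sd * rng.standard_normal()))
        v_rub *= float(np.exp(jitter_sd * rng.standard_normal()))
    return LeafParameters(
        g_sw=0.6, g_mw=10.0,
        ca=CAKinetics(v_max_ca=v_ca, t_eq_ca=39.7),
        rub=RubiscoKinetics(v_max_rub=v_rub, dH_a_rub=54_500.0),
        gamma=GammaCosSpec.s2(m_cos=22.4, t_ref_gamma=16.4),
    )


def hash_stable(s: str) -> int:
    """Deterministic string hash (Python's hash() is salted per process)."""
    out = 0
    for ch in str(s):
        out = (out * 131 + ord(ch)) % (2**31 - 1)
    return out


def generate_dataset(design: ExperimentDesign, leaf_truth: LeafParameters,
                     cfg: Optional[ChamberConfig] = None,
                     noise: Optional[NoiseModel] = None,
                     emission: Optional[ChamberEmissionModel] = None,
                     seed: int = 0, point_id_offset: int = 0):
    """Generate one experiment's observed points plus the ground truth.

    Returns ``(data, truth)``: ``data`` follows the observed-point CSV
    schema; ``truth`` carries per-point true g_sw, the noise-free outflows
    and fluxes, and the chamber emission flux added to each point.
    """
    noise = NoiseModel() if noise is None else noise
    emission = ChamberEmissionModel() if emission is None else emission
    c = design.constants
    cfg = cfg if cfg is not None else ChamberConfig(
        af=c["af_mol_s"], s=c["s_m2"], p_air=c["p_air_Pa"], g_bw=c["g_bw"])
    n = len(design.levels)
    cos_in = np.full(n, c.get("cos_in_dry", np.nan))
    t_leaf = np.full(n, c.get("t_leaf_C", np.nan))
    g_sw = np.full(n, c.get("g_sw", np.nan))
    if design.kind == "cos_ramp":
        cos_in = design.levels
    elif design.kind == "gsw_sweep":
        g_sw = design.levels
    else:
        t_leaf = design.levels
    rng = np.random.default_rng(seed)
    sim = forward_simulate(cfg, replace(leaf_truth, g_sw=g_sw), cos_in,
                           c["co2_in_dry"], c["h2o_in"], t_leaf)
    q = cfg.q
    # Chamber emission enters the balance as an extra COS source: on the
    # measurement basis it raises the outflow by F_emis / (AF/S).
    f_emis = emission.emission(t_leaf)
    if emission.resid_sd > 0:
        f_emis = f_emis + emission.resid_sd * rng.standard_normal(n)
    cos_out = np.asarray(sim.cos_out_dry) + f_emis / q
    co2_out = np.asarray(sim.co2_out_dry)
    h2o_out = np.asarray(sim.h2o_out)
    data = pd.DataFrame({
        "point_id": [f"{design.plant_id}-{design.kind}-{i + point_id_offset:03d}"
                     for i in range(n)],
        "plant_id": design.plant_id,
        "t_leaf_C": t_leaf,
        "p_air_Pa": cfg.p_air,
        "af_mol_s": cfg.af,
        "s_m2": cfg.s,
        "g_bw": cfg.g_bw,
        "g_sw_meas": g_sw + noise.sigma_g_sw_meas * rng.standard_normal(n),
        "cos_in_dry": cos_in,
        "cos_out_dry": cos_out + noise.sigma_cos * rng.standard_normal(n),
        "co2_in_dry": np.full(n, float(c["co2_in_dry"])),
        "co2_out_dry": co2_out + noise.sigma_co2 * rng.standard_normal(n),
        "h2o_in": np.full(n, float(c["h2o_in"])),
        "h2o_out": h2o_out + noise.sigma_h2o * rng.standard_normal(n),
        "sigma_cos": max(noise.sigma_cos, 1e-9),
        "sigma_co2": max(noise.sigma_co2, 1e-9),
        "sigma_h2o": max(noise.sigma_h2o, 1e-9),
    })
    truth = pd.DataFrame({
        "point_id": data["point_id"],
        "plant_id": design.plant_id,
        "g_sw_true": g_sw,
        "cos_out_true": cos_out,       # emission included, noise-free
        "cos_out_leaf_only": np.asarray(sim.cos_out_dry),
        "co2_out_true": co2_out,
        "h2o_out_true": h2o_out,
        "f_cos_true": np.asarray(sim.f_cos),
        "f_co2_true": np.asarray(sim.f_co2),
        "f_emission": f_emis,
    })
    return lio.validate_dataset(data), truth


def correct_chamber_flux(f_obs, t_air, emission: ChamberEmissionModel):
    """Add back the temperature-predicted chamber emission to an apparent
    leaf COS flux (the emission masks uptake); exact inverse of the
    generator's emission injection when the residual scatter is zero."""
    return np.asarray(f_obs, dtype=float) + emission.emission(t_air)


def apply_emission_correction(data: pd.DataFrame,
                              emission: ChamberEmissionModel) -> pd.DataFrame:
    """Observational preprocessing: remove the temperature-predicted
    chamber COS source from the outflow record, so downstream analysis sees
    leaf-only exchange.  On the measurement basis this lowers cos_out_dry
    by F_emis / (AF/S); equivalent to :func:`correct_chamber_flux` on the
    chamber-balance flux."""
    out = data.copy()
    q = np.asarray(data["af_mol_s"], float) / np.asarray(data["s_m2"], float)
    out["cos_out_dry"] = (np.asarray(data["cos_out_dry"], float)
                          - emission.emission(data["t_leaf_C"]) / q)
    return out


def generate_experiment_suite(seed: int = 0, leaf_truth=None,
                              noise: Optional[NoiseModel] = None,
                              emission: Optional[ChamberEmissionModel] = None,
                              jitter_plants: bool = True,
                              n_gsw: int = 8, n_temp: int = 12):
    """The stomatal-sweep and temperature-sweep campaign: three plants
    swept in g_sw near 25 degC, two of them swept in temperature at fixed
    g_sw (48 points at the defaults).  Returns (data, truth) frames."""
    noise = NoiseModel() if noise is None else noise
    emission = ChamberEmissionModel() if emission is None else emission
    designs = [
        ExperimentDesign.gsw_sweep("sunflower2", levels=np.linspace(0.4, 1.1, n_gsw),
                                   cos_in_dry=1096.0),
        ExperimentDesign.gsw_sweep("sunflower3", levels=np.linspace(0.3, 1.0, n_gsw),
                                   cos_in_dry=1182.0),
        ExperimentDesign.gsw_sweep("sunflower4", levels=np.linspace(0.3, 0.6, n_gsw),
                                   cos_in_dry=914.0),
        ExperimentDesign.temp_sweep("sunflower2", levels=np.linspace(19.1, 30.9, n_temp),
                                    cos_in_dry=1088.0),
        ExperimentDesign.temp_sweep("sunflower4", levels=np.linspace(19.0, 29.8, n_temp),
                                    cos_in_dry=927.0),
    ]
    data_parts, truth_parts = [], []
    for i, design in enumerate(designs):
        if leaf_truth is None:
            leaf = default_truth(design.plant_id, seed_jitter=jitter_plants)
        else:
            leaf = leaf_truth
        d, t = generate_dataset(design, leaf, noise=noise, emission=emission,
                                seed=seed * 1000 + i, point_id_offset=100 * i)
        data_parts.append(d)
        truth_parts.append(t)
    data = pd.concat(data_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    return lio.validate_dataset(data), truth
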