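"""Weighted least-squares state inversion of the cuvette model.

The estimation problem: given per-interval observations of inflowing and
outflowing COS, CO2 and H2O mole fractions (with per-point measurement
sigmas), recover the leaf physiological state - CA capacity and optimum
temperature, the compensation-point temperature parameter, RuBisCO capacity
and activation energy, and per-point stomatal conductance - by minimizing a
weighted cost

    J_tot = J_bg + J_COS + J_CO2 + J_H2O,

where J_bg penalizes departure of the state x from its prior x_a in units
of the prior sigma, and each observational term sums squared misfits
between the forward-modeled and observed outflow mole fractions (dry-air
basis, the measurement basis), normalized by sigma^2 and *divided* by a
per-gas weight W.  Larger W therefore down-weights a gas; the weights exist
to stop the extremely precise CO2 data from dominating the fit.

The public surface follows the Model/Results convention: build a
:class:`CuvetteInversion` from a data frame, call :meth:`~CuvetteInversion.fit`,
get a :class:`CuvetteInversionResults` carrying estimates, diagnostics and a
``summary()`` table; Monte Carlo uncertainty hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import io as lio
from .cuvette import ChamberConfig, LeafParameters, forward_simulate
from .kinetics import CAKinetics, CO2Constants, GammaCosSpec, RubiscoKinetics

__all__ = [
    "StateVector",
    "PriorSpec",
    "WeightSet",
    "CostBreakdown",
    "chi2",
    "select_weights",
    "CuvetteInversion",
    "CuvetteInversionResults",
]

# Prior means and sigmas of the shared state entries (per-plant V_max values
# share one prior).  dH entries are carried in kJ mol-1 in the state so all
# entries have comparable magnitude.
PRIOR_V_MAX_CA = (0.125, 0.060)      # mol m-2 s-1
PRIOR_T_EQ_CA = (30.0, 15.0)         # degC
PRIOR_M_COS = (16.2, 16.2)           # pmol mol-1 K-1 (S2)
PRIOR_DH_GAMMA = (134.3, 134.3)      # kJ mol-1 (S3/S4)
PRIOR_V_MAX_RUB = (90.0, 20.0)       # umol m-2 s-1
PRIOR_DH_RUB = (60.0, 12.0)          # kJ mol-1

BOUNDS_V_MAX_CA = (0.01, 0.50)
BOUNDS_V_MAX_RUB = (1.0, 200.0)
BOUNDS_T_EQ_CA = (1.0, 60.0)
BOUNDS_GAMMA_PARAM = (1.0, 300.0)
BOUNDS_DH_RUB = (1.0, 100.0)
BOUNDS_G_SW = (0.0, 3.0)

# g_sw prior sigma composition: run-to-run variability, instrument bias
# allowance, and the per-point relative H2O measurement error.
G_SW_SIGMA_VARIABILITY = 0.08
G_SW_SIGMA_INSTRUMENT = 0.02


@dataclass
class WeightSet:
    """Per-part cost weights.  They sit beside sigma^2 in the denominator,
    so a larger weight *shrinks* that part of the cost."""

    w_bg: float = 1.0
    w_cos: float = 0.034
    w_co2: float = 7.2
    w_h2o: float = 3.24

    def __post_init__(self):
        for name in ("w_bg", "w_cos", "w_co2", "w_h2o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def unit(cls):
        return cls(w_bg=1.0, w_cos=1.0, w_co2=1.0, w_h2o=1.0)


def chi2(j_part: float, n: int) -> float:
    """Reduced cost: a partial cost divided by its observation (or state)
    count.  Near 1 after fitting means the model sits inside the error
    distribution; well below 1 suggests overfitting."""
    if n <= 0:
        raise ValueError("count must be positive")
    return j_part / n


def select_weights(unweighted_chi2: dict, targets: dict) -> WeightSet:
    """Choose per-gas weights so that the weighted prior chi^2 of each gas
    equals its target: w_gas = chi2_unweighted / chi2_target."""
    kwargs = {"w_bg": 1.0}
    for gas in ("cos", "co2", "h2o"):
        target = targets[gas]
        if target <= 0:
            raise ValueError("chi2 targets must be positive")
        kwargs[f"w_{gas}"] = unweighted_chi2[gas] / target
    return WeightSet(**kwargs)


@dataclass
class StateVector:
    """Structured view of the optimization state.

    Per-plant entries: v_max_ca (mol m-2 s-1), v_max_rub (umol m-2 s-1).
    Shared entries: t_eq_ca (degC), gamma_param (m_COS in pmol mol-1 K-1
    for the linear variant, or dH_a,Gamma in kJ mol-1 for the Arrhenius
    variants; absent for the no-compensation-point variant), dH_a_rub
    (kJ mol-1).  Per-point entries: g_sw (mol m-2 s-1).
    """

    plants: tuple
    variant: str
    v_max_ca: np.ndarray
    v_max_rub: np.ndarray
    t_eq_ca: float
    gamma_param: Optional[float]
    dH_a_rub: float
    g_sw: np.ndarray

    @property
    def has_gamma(self) -> bool:
        return self.variant != "S1"

    @property
    def names(self) -> list:
        out = [f"v_max_ca[{p}]" for p in self.plants]
        out += [f"v_max_rub[{p}]" for p in self.plants]
        out.append("t_eq_ca")
        if self.has_gamma:
            out.append("m_cos" if self.variant == "S2" else "dH_a_gamma")
        out.append("dH_a_rub")
        out += [f"g_sw[{i}]" for i in range(len(self.g_sw))]
        return out

    def pack(self) -> np.ndarray:
        head = [self.t_eq_ca]
        if self.has_gamma:
            head.append(self.gamma_param)
        head.append(self.dH_a_rub)
        return np.concatenate([self.v_max_ca, self.v_max_rub, head, self.g_sw])

    def unpack(self, vec: np.ndarray) -> "StateVector":
        """New StateVector with the same block structure, values from
        ``vec``; pack/unpack round-trips exactly."""
        n_p = len(self.plants)
        vec = np.asarray(vec, dtype=float)
        i = 0
        v_ca = vec[i:i + n_p]; i += n_p
        v_rub = vec[i:i + n_p]; i += n_p
        t_eq = float(vec[i]); i += 1
        gp = None
        if self.has_gamma:
            gp = float(vec[i]); i += 1
        dh = float(vec[i]); i += 1
        g_sw = vec[i:]
        if len(g_sw) != len(self.g_sw):
            raise ValueError("state vector length mismatch")
        return replace(self, v_max_ca=v_ca, v_max_rub=v_rub, t_eq_ca=t_eq,
                       gamma_param=gp, dH_a_rub=dh, g_sw=g_sw)

    def bounds(self) -> list:
        n_p = len(self.plants)
        out = [BOUNDS_V_MAX_CA] * n_p + [BOUNDS_V_MAX_RUB] * n_p
        out.append(BOUNDS_T_EQ_CA)
        if self.has_gamma:
            out.append(BOUNDS_GAMMA_PARAM)
        out.append(BOUNDS_DH_RUB)
        out += [BOUNDS_G_SW] * len(self.g_sw)
        return out

    def gamma_spec(self) -> GammaCosSpec:
        if self.variant == "S1":
            return GammaCosSpec.s1()
        if self.variant == "S2":
            return GammaCosSpec.s2(m_cos=self.gamma_param)
        if self.variant == "S3":
            return GammaCosSpec.s3(dH_a_gamma=self.gamma_param * 1000.0)
        return GammaCosSpec.s4(dH_a_gamma=self.gamma_param * 1000.0)

    def series(self) -> pd.Series:
        return pd.Series(self.pack(), index=self.names)


@dataclass
class PriorSpec:
    """Prior mean and sigma for every state entry, in state layout."""

    mean: StateVector
    sigma: StateVector

    @classmethod
    def from_dataset(cls, data: pd.DataFrame, variant: str = "S2") -> "PriorSpec":
        """Default priors: literature-derived values for the shared
        physiology, measured values for the per-point g_sw with a composed
        sigma of run-to-run variability, instrument allowance and the
        normalized per-point H2O measurement error."""
        plants = tuple(pd.unique(data["plant_id"]))
        n_p = len(plants)
        g_sw_meas = np.asarray(data["g_sw_meas"], dtype=float)
        g_sw_sigma = np.sqrt(
            G_SW_SIGMA_VARIABILITY**2
            + G_SW_SIGMA_INSTRUMENT**2
            + (g_sw_meas * np.asarray(data["sigma_h2o"], float)
               / np.asarray(data["h2o_out"], float)) ** 2
        )
        if variant == "S1":
            gp_mean, gp_sigma = None, None
        elif variant == "S2":
            gp_mean, gp_sigma = PRIOR_M_COS
        else:
            gp_mean, gp_sigma = PRIOR_DH_GAMMA
        mean = StateVector(
            plants=plants, variant=variant,
            v_max_ca=np.full(n_p, PRIOR_V_MAX_CA[0]),
            v_max_rub=np.full(n_p, PRIOR_V_MAX_RUB[0]),
            t_eq_ca=PRIOR_T_EQ_CA[0], gamma_param=gp_mean,
            dH_a_rub=PRIOR_DH_RUB[0], g_sw=g_sw_meas.copy(),
        )
        sigma = StateVector(
            plants=plants, variant=variant,
            v_max_ca=np.full(n_p, PRIOR_V_MAX_CA[1]),
            v_max_rub=np.full(n_p, PRIOR_V_MAX_RUB[1]),
            t_eq_ca=PRIOR_T_EQ_CA[1], gamma_param=gp_sigma,
            dH_a_rub=PRIOR_DH_RUB[1], g_sw=g_sw_sigma,
        )
        if np.any(sigma.pack() <= 0):
            raise ValueError("prior sigmas must be strictly positive")
        return cls(mean=mean, sigma=sigma)


@dataclass
class CostBreakdown:
    """Cost-function decomposition at one state."""

    j_bg: float
    j_cos: float
    j_co2: float
    j_h2o: float
    n_state: int
    n_points: int

    @property
    def j_tot(self) -> float:
        return self.j_bg + self.j_cos + self.j_co2 + self.j_h2o

    def chi2_table(self) -> pd.Series:
        return pd.Series({
            "bg": chi2(self.j_bg, self.n_state),
            "cos": chi2(self.j_cos, self.n_points),
            "co2": chi2(self.j_co2, self.n_points),
            "h2o": chi2(self.j_h2o, self.n_points),
        })


class CuvetteInversion:
    """Weighted nonlinear inversion of the steady-state cuvette model.

    Parameters
    ----------
    data : DataFrame in the observed-point schema (one row per 150-s
        steady-state interval).
    prior : PriorSpec, defaults to the literature/measurement priors via
        :meth:`PriorSpec.from_dataset`.
    weights : WeightSet, defaults to the balanced set (chi2_prior targets
        30/100/3 for COS/CO2/H2O on the study data).
    gamma_variant : which compensation-point temperature function the model
        carries ("S1".."S4").
    """

    def __init__(self, data: pd.DataFrame, prior: Optional[PriorSpec] = None,
                 weights: Optional[WeightSet] = None, gamma_variant: str = "S2",
                 g_mw: float = 10.0, co2_constants: Optional[CO2Constants] = None):
        self.data = lio.validate_dataset(data).reset_index(drop=True)
        self.gamma_variant = gamma_variant
        self.weights = weights if weights is not None else WeightSet()
        self.prior = prior if prior is not None else PriorSpec.from_dataset(
            self.data, variant=gamma_variant)
        if self.prior.mean.variant != gamma_variant:
            raise ValueError("prior variant does not match gamma_variant")
        self.g_mw = g_mw
        self.co2_constants = co2_constants if co2_constants is not None else CO2Constants()
        d = self.data
        self._cfg = ChamberConfig(
            af=np.asarray(d["af_mol_s"], float), s=np.asarray(d["s_m2"], float),
            p_air=np.asarray(d["p_air_Pa"], float), g_bw=np.asarray(d["g_bw"], float),
        )
        self._t_leaf = np.asarray(d["t_leaf_C"], float)
        plant_order = {p: i for i, p in enumerate(self.prior.mean.plants)}
        self._plant_idx = np.array([plant_order[p] for p in d["plant_id"]])
        self._obs = {g: np.asarray(d[c], float) for g, c in
                     (("cos", "cos_out_dry"), ("co2", "co2_out_dry"), ("h2o", "h2o_out"))}
        self._sigma = {g: np.asarray(d[c], float) for g, c in
                       (("cos", "sigma_cos"), ("co2", "sigma_co2"), ("h2o", "sigma_h2o"))}

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CuvetteInversion":
        return cls(lio.read_dataset(path), **kwargs)

    # statsmodels-flavoured alias
    @classmethod
    def from_dataframe(cls, data, **kwargs) -> "CuvetteInversion":
        return cls(data, **kwargs)

    @property
    def n_points(self) -> int:
        return len(self.data)

    @property
    def n_state(self) -> int:
        return len(self.prior.mean.pack())

    def leaf_parameters(self, state: StateVector) -> LeafParameters:
        """Array-backed LeafParameters mapping per-plant and per-point state
        entries onto the data rows.

        g_sw is floored at 1e-9: the optimizer's lower bound is a closed
        stomate, where the conductance chain is singular but the fluxes have
        a well-defined zero limit.
        """
        return LeafParameters(
            g_sw=np.maximum(state.g_sw, 1e-9),
            g_mw=self.g_mw,
            ca=CAKinetics(v_max_ca=state.v_max_ca[self._plant_idx],
                          t_eq_ca=state.t_eq_ca),
            rub=RubiscoKinetics(v_max_rub=state.v_max_rub[self._plant_idx],
                                dH_a_rub=state.dH_a_rub * 1000.0),
            co2c=self.co2_constants,
            gamma=state.gamma_spec(),
        )

    def simulate(self, state: StateVector, measurement_basis: bool = True):
        """Forward-simulate every data point at the given state.

        ``measurement_basis`` converts modeled outflows to dry air with the
        *observed* outflow humidity (the basis on which the cost compares
        model and data); otherwise the model's own H2O solution is used.
        """
        leaf = self.leaf_parameters(state)
        d = self.data
        return forward_simulate(
            self._cfg, leaf,
            np.asarray(d["cos_in_dry"], float), np.asarray(d["co2_in_dry"], float),
            np.asarray(d["h2o_in"], float), self._t_leaf,
            h2o_out_obs=self._obs["h2o"] if measurement_basis else None,
        )

    def cost(self, state, weights: Optional[WeightSet] = None) -> CostBreakdown:
        """Evaluate the cost decomposition at a state (StateVector or packed
        vector)."""
        if not isinstance(state, StateVector):
            state = self.prior.mean.unpack(np.asarray(state, dtype=float))
        w = weights if weights is not None else self.weights
        sim = self.simulate(state)
        est = {"cos": sim.cos_out_dry, "co2": sim.co2_out_dry, "h2o": sim.h2o_out}
        parts = {}
        for gas, w_gas in (("cos", w.w_cos), ("co2", w.w_co2), ("h2o", w.w_h2o)):
            r = est[gas] - self._obs[gas]
            parts[gas] = float(np.sum(r * r / (w_gas * self._sigma[gas] ** 2)))
        dx = state.pack() - self.prior.mean.pack()
        j_bg = float(np.sum(dx * dx / (w.w_bg * self.prior.sigma.pack() ** 2)))
        return CostBreakdown(j_bg=j_bg, j_cos=parts["cos"], j_co2=parts["co2"],
                             j_h2o=parts["h2o"], n_state=self.n_state,
                             n_points=self.n_points)

    def objective(self, x: np.ndarray) -> float:
        """Total cost as a function of the packed state vector."""
        return self.cost(x).j_tot

    def prior_chi2(self, weights: Optional[WeightSet] = None) -> pd.Series:
        """Reduced per-part cost at the prior mean (J_bg is zero there by
        construction)."""
        return self.cost(self.prior.mean, weights=weights).chi2_table()

    def fit(self, start: Optional[StateVector] = None, maxiter: int = 500,
            ftol: float = 1e-10) -> "CuvetteInversionResults":
        """Minimize J_tot with a bounded gradient-based optimizer (SLSQP),
        starting from the prior mean unless told otherwise.  Non-convergence
        is reported on the results object; the best iterate is returned."""
        x0 = (start.pack() if isinstance(start, StateVector)
              else np.asarray(start, float) if start is not None
              else self.prior.mean.pack())
        opts = {"maxiter": maxiter, "ftol": ftol}
        bounds = self.prior.mean.bounds()
        res = minimize(self.objective, x0, method="SLSQP", bounds=bounds,
                       options=opts)
        success, n_iter, message = bool(res.success), int(res.get("nit", -1)), \
            str(res.message)
        if not success:
            # polish from the best iterate; a fresh start often clears a
            # spurious line-search failure
            res2 = minimize(self.objective, res.x, method="SLSQP", bounds=bounds,
                            options=opts)
            if res2.fun <= res.fun:
                res = res2
                success, message = bool(res2.success), str(res2.message)
                n_iter += int(res2.get("nit", 0))
        if not success and res.fun <= 1e-9:
            # every cost term is non-negative, so an (essentially) zero cost
            # is the global minimum regardless of the optimizer's verdict
            success, message = True, "zero-cost global minimum"
        state = self.prior.mean.unpack(res.x)
        return CuvetteInversionResults(
            model=self, params=state, cost=self.cost(state),
            prior_cost=self.cost(self.prior.mean),
            converged=success, n_iter=n_iter, message=message,
        )


@dataclass
class CuvetteInversionResults:
    """Posterior state and fit diagnostics of a cuvette inversion."""

    model: CuvetteInversion
    params: StateVector
    cost: CostBreakdown
    prior_cost: CostBreakdown
    converged: bool
    n_iter: int
    message: str
    ensemble: Optional[object] = field(default=None, repr=False)

    @property
    def j_tot(self) -> float:
        return self.cost.j_tot

    def chi2_table(self) -> pd.DataFrame:
        return pd.DataFrame({"prior": self.prior_cost.chi2_table(),
                             "posterior": self.cost.chi2_table()})

    def predict(self, measurement_basis: bool = True):
        """Forward simulation of every data point at the posterior state."""
        return self.model.simulate(self.params, measurement_basis=measurement_basis)

    def error_stats(self) -> pd.DataFrame:
        """RMSE and MBE of modeled against observed outflow mole fractions,
        prior and posterior."""
        from .uncertainty import error_stats
        rows = {}
        for label, state in (("prior", self.model.prior.mean), ("posterior", self.params)):
            sim = self.model.simulate(state)
            est = {"cos": sim.cos_out_dry, "co2": sim.co2_out_dry, "h2o": sim.h2o_out}
            for gas in ("cos", "co2", "h2o"):
                rmse, mbe = error_stats(est[gas], self.model._obs[gas])
                rows[(label, gas)] = {"rmse": rmse, "mbe": mbe}
        return pd.DataFrame(rows).T

    def monte_carlo(self, n_members: int = 200, seed: int = 0, **kwargs):
        """Monte Carlo posterior ensemble (see
        :func:`leafcos.uncertainty.monte_carlo_posterior`); cached on the
        results object."""
        from .uncertainty import monte_carlo_posterior
        self.ensemble = monte_carlo_posterior(self.model, n_members=n_members,
                                              seed=seed, **kwargs)
        return self.ensemble

    def leaf_for_plant(self, plant_id, g_sw: float = 0.6) -> LeafParameters:
        """Scalar LeafParameters for one plant at a nominal g_sw, e.g. for
        response-curve simulations."""
        i = self.params.plants.index(plant_id)
        return LeafParameters(
            g_sw=g_sw, g_mw=self.model.g_mw,
            ca=CAKinetics(v_max_ca=float(self.params.v_max_ca[i]),
                          t_eq_ca=self.params.t_eq_ca),
            rub=RubiscoKinetics(v_max_rub=float(self.params.v_max_rub[i]),
                                dH_a_rub=self.params.dH_a_rub * 1000.0),
            co2c=self.model.co2_constants,
            gamma=self.params.gamma_spec(),
        )

    def summary(self) -> str:
        lines = [
            "Cuvette state inversion (" + self.model.gamma_variant + ")",
            f"  points: {self.model.n_points}   state entries: {self.model.n_state}"
            f"   plants: {list(self.params.plants)}",
            f"  converged: {self.converged} ({self.message}), {self.n_iter} iterations",
            f"  J_tot: prior {self.prior_cost.j_tot:.1f} -> posterior {self.cost.j_tot:.1f}",
            "",
            "  chi^2 (reduced cost)    prior   posterior",
        ]
        tab = self.chi2_table()
        for part in tab.index:
            lines.append(f"    {part:<18} {tab.loc[part, 'prior']:>9.2f} "
                         f"{tab.loc[part, 'posterior']:>9.2f}")
        lines.append("")
        lines.append("  parameter            prior      posterior")
        prior = self.model.prior.mean
        for name, a, b in zip(prior.names, prior.pack(), self.params.pack()):
            if name.startswith("g_sw["):
                continue
            lines.append(f"    {name:<18} {a:>9.4g} {b:>12.4g}")
        g = self.params.g_sw
        lines.append(f"    g_sw (mean of {len(g)})  "
                     f"{np.mean(prior.g_sw):>8.4g} {np.mean(g):>12.4g}")
        return "\n".join(lines)
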