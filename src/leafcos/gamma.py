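"""COS compensation-point estimation.

Two observation-side routes to the compensation point Gamma_COS complement
the model-side temperature functions in :mod:`leafcos.kinetics`:

* the regression route (concentration-ramp experiments): net COS flux rises
  linearly with the outflowing COS mole fraction, and Gamma_COS is the
  extrapolated x-intercept where the flux crosses zero, with a 95 % CI from
  the regression covariance and an optional widening for residual chamber
  background variability;
* the indirect route (any experiment): with optimized model parameters, the
  chamber and layer balances invert algebraically from the measured in/out
  mole fractions down to the mesophyll-level [COS]_c, which at steady state
  is the compensation point itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cuvette import (
    RATIO_B_COS,
    RATIO_S_COS,
    ChamberConfig,
    LeafParameters,
    dry_to_wet,
    solve_h2o,
)
from .kinetics import g_m_cos

__all__ = [
    "RegressionGammaResult",
    "IndirectGammaPoint",
    "line_through_points",
    "regress_gamma",
    "widen_ci_with_chamber_residual",
    "indirect_gamma",
    "indirect_gamma_dataset",
]


@dataclass
class RegressionGammaResult:
    """X-intercept estimate of the compensation point from a flux-versus-
    concentration regression.

    gamma_hat : pmol mol-1, concentration at which the fitted net flux
        crosses zero (-intercept/slope).
    ci95_half_width : pmol mol-1, half width of the 95 % confidence interval.
    slope : pmol m-2 s-1 per pmol mol-1.
    """

    gamma_hat: float
    ci95_half_width: float
    slope: float
    intercept: float
    n_points: int
    t_leaf: Optional[float] = None
    method: str = "delta"
    # Regression internals kept for uncertainty widening.
    resid_var: float = 0.0
    xtx_inv: Optional[np.ndarray] = None
    extra_var: float = 0.0


def line_through_points(p1, p2):
    """Slope (pmol mol-1 K-1) and zero-crossing temperature (degC) of the
    line through two (temperature, compensation point) pairs.

    This is how the linear prior temperature function of Gamma_COS is built
    from two regression-derived anchors.
    """
    (t1, g1), (t2, g2) = p1, p2
    if t1 == t2:
        raise ValueError("anchor temperatures must differ")
    slope = (g2 - g1) / (t2 - t1)
    if slope == 0:
        raise ValueError("zero slope has no finite zero-crossing")
    t_ref = t1 - g1 / slope
    return slope, t_ref


def _gamma_ci(gamma_hat, slope, intercept, cov, dof, method):
    tq = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    if method == "delta":
        jac = np.array([-1.0 / slope, intercept / slope**2])
        var = float(jac @ cov @ jac)
        return tq * np.sqrt(max(var, 0.0))
    if method == "fieller":
        # {g : (b0 + b1 g)^2 <= t^2 (v00 + 2 g v01 + g^2 v11)}
        v00, v01, v11 = cov[0, 0], cov[0, 1], cov[1, 1]
        a = slope**2 - tq**2 * v11
        b = 2.0 * (intercept * slope - tq**2 * v01)
        c = intercept**2 - tq**2 * v00
        disc = b * b - 4.0 * a * c
        if a <= 0 or disc < 0:
            return np.inf  # unbounded Fieller set
        lo = (-b - np.sqrt(disc)) / (2.0 * a)
        hi = (-b + np.sqrt(disc)) / (2.0 * a)
        return 0.5 * (hi - lo)
    raise ValueError(f"unknown CI method {method!r}")


def regress_gamma(points, t_leaf=None, method="delta") -> RegressionGammaResult:
    """OLS fit of net COS flux against outflowing COS mole fraction; the
    compensation point is the fitted zero-flux concentration.

    ``points`` is an iterable of (cos_out [pmol mol-1], f_cos
    [pmol m-2 s-1]) pairs, at least three, with spread in the abscissa.
    The 95 % CI of the x-intercept comes from first-order (delta-method)
    propagation of the coefficient covariance with a t quantile at n-2
    degrees of freedom; ``method="fieller"`` gives the exact ratio interval
    instead.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (cos_out, f_cos) pairs")
    if len(pts) < 3:
        raise ValueError("need at least 3 points for the intercept regression")
    conc, flux = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate design: no spread in cos_out")
    x = sm.add_constant(conc)
    fit = sm.OLS(flux, x).fit()
    intercept, slope = fit.params
    if slope <= 0:
        raise ValueError(
            f"non-positive slope ({slope:.3g}); x-intercept is not a compensation point"
        )
    gamma_hat = -intercept / slope
    xtx_inv = np.linalg.inv(x.T @ x)
    resid_var = float(fit.ssr / fit.df_resid) if fit.df_resid > 0 else 0.0
    cov = resid_var * xtx_inv
    half = _gamma_ci(gamma_hat, slope, intercept, cov, int(fit.df_resid), method)
    return RegressionGammaResult(
        gamma_hat=float(gamma_hat),
        ci95_half_width=float(half),
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(pts),
        t_leaf=t_leaf,
        method=method,
        resid_var=resid_var,
        xtx_inv=xtx_inv,
    )


def widen_ci_with_chamber_residual(result: RegressionGammaResult,
                                   resid_sd_flux: float,
                                   resid_sd_conc: float) -> RegressionGammaResult:
    """Recompute the CI with extra per-point variance from the residual
    empty-chamber background correction.

    The background correction leaves residual scatter both in the flux
    (``resid_sd_flux``, pmol m-2 s-1) and in the ambient concentration
    (``resid_sd_conc``, pmol mol-1); the latter enters the flux axis through
    the regression slope.  Both inflate the per-point variance of the fit,
    so the widened interval is never narrower than the original.
    """
    if resid_sd_flux < 0 or resid_sd_conc < 0:
        raise ValueError("residual standard deviations must be non-negative")
    if result.xtx_inv is None:
        raise ValueError("result carries no regression internals to widen")
    extra = resid_sd_flux**2 + (result.slope * resid_sd_conc) ** 2
    total_extra = result.extra_var + extra
    cov = (result.resid_var + total_extra) * result.xtx_inv
    dof = result.n_points - 2
    half = _gamma_ci(result.gamma_hat, result.slope, result.intercept, cov,
                     dof, result.method)
    return replace(result, ci95_half_width=float(half), extra_var=total_extra)


@dataclass
class IndirectGammaPoint:
    """Layer COS mole fractions recovered from one measured interval; at
    steady state ``cos_c`` is the compensation point seen by the mesophyll."""

    cos_b: float
    cos_i: float
    cos_c: float
    point_id: object = None
    t_leaf: Optional[float] = None


def indirect_gamma(row, leaf: LeafParameters, cfg: ChamberConfig,
                   g_sw=None) -> IndirectGammaPoint:
    """Invert the chamber and layer balances from measured COS in/out mole
    fractions down to the mesophyll level.

    ``row`` is a mapping with the observed-point schema fields (a pandas
    Series works).  ``leaf`` carries the optimized parameters; ``g_sw``
    overrides the stomatal conductance (the optimized per-point value).
    The transpiration used in the ternary terms comes from the H2O model
    with the optimized g_sw and the observed inflowing humidity - not from
    the measured outflow - so the inversion is consistent with the
    optimized state.  Applied to noise-free forward-model output with the
    same parameters this returns Gamma_COS(T) exactly.
    """
    g_sw_eff = float(leaf.g_sw if g_sw is None else g_sw)
    if g_sw_eff <= 0 or cfg.g_bw <= 0:
        raise ValueError("conductances must be positive")
    t_leaf = float(row["t_leaf_C"])
    q = cfg.q
    g_b = cfg.g_bw / RATIO_B_COS
    g_s = g_sw_eff / RATIO_S_COS
    cos_in = dry_to_wet(float(row["cos_in_dry"]), float(row["h2o_in"]))
    cos_a = dry_to_wet(float(row["cos_out_dry"]), float(row["h2o_out"]))
    h2o = solve_h2o(cfg, leaf, float(row["h2o_in"]), t_leaf, g_sw=g_sw_eff)
    e = -net_flux_h2o(q, float(row["h2o_in"]), h2o.x_a) / 1000.0
    cos_b = cos_a + (q / g_b) * (cos_a - cos_in)
    cos_i = (-g_b * cos_a + g_b * cos_b + g_s * cos_b - 0.5 * e * cos_b) / (
        g_s + 0.5 * e
    )
    g_m = g_m_cos(t_leaf, leaf.ca)
    if np.asarray(g_m).min() <= 0:
        raise ValueError("mesophyll conductance must be positive")
    cos_c = (
        -(g_s / g_m) * (cos_b - cos_i)
        + e / (2.0 * g_m) * (cos_b + cos_i)
        + cos_i
    )
    return IndirectGammaPoint(
        cos_b=float(cos_b), cos_i=float(cos_i), cos_c=float(cos_c),
        point_id=row.get("point_id") if hasattr(row, "get") else None,
        t_leaf=t_leaf,
    )


def net_flux_h2o(q, x_in, x_a):
    """Chamber balance flux for H2O (mmol m-2 s-1, uptake-positive)."""
    return q * (x_in - x_a)


def indirect_gamma_dataset(df: pd.DataFrame, leaf: LeafParameters,
                           g_sw_opt=None) -> pd.DataFrame:
    """Apply the indirect inversion to every row of an observed-point
    frame; returns a copy with ``cos_b``, ``cos_i``, ``cos_c`` appended.

    ``g_sw_opt`` is an array of optimized per-point stomatal conductances
    aligned with the rows (defaults to the measured ``g_sw_meas`` column).
    """
    g_sw_opt = (np.asarray(df["g_sw_meas"], dtype=float)
                if g_sw_opt is None else np.asarray(g_sw_opt, dtype=float))
    out = df.copy()
    cols = {"cos_b": [], "cos_i": [], "cos_c": []}
    for (_, row), g_sw in zip(df.iterrows(), g_sw_opt):
        cfg = ChamberConfig(af=row["af_mol_s"], s=row["s_m2"],
                            p_air=row["p_air_Pa"], g_bw=row["g_bw"])
        pt = indirect_gamma(row, leaf, cfg, g_sw=g_sw)
        cols["cos_b"].append(pt.cos_b)
        cols["cos_i"].append(pt.cos_i)
        cols["cos_c"].append(pt.cos_c)
    for k, v in cols.items():
        out[k] = v
    return out
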