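"""Monte Carlo posterior ensembles and forward uncertainty propagation.

The inversion returns a point estimate only; its uncertainty is estimated
by re-optimizing an ensemble of perturbed problems (noise added to both the
prior means and the observations, each within its own sigma) and taking the
spread and covariance of the ensemble members as the posterior spread and
covariance.  Forward uncertainty at a reference chamber condition comes
from correlated Gaussian parameter draws around the ensemble mean with the
ensemble covariance, trimmed at three standard deviations per component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cuvette import ChamberConfig, LeafParameters, forward_simulate
from .kinetics import CAKinetics, GammaCosSpec, RubiscoKinetics

__all__ = [
    "PosteriorEnsemble",
    "ForwardSpread",
    "CANONICAL_CONDITION",
    "error_stats",
    "monte_carlo_posterior",
    "forward_spread",
]

#: Reference chamber condition for forward-spread simulations.
CANONICAL_CONDITION = {
    "p_air": 103_100.0,     # Pa
    "af": 3.5e-4,           # mol s-1
    "s": 9e-4,              # m2
    "co2_in_dry": 400.0,    # umol mol-1
    "cos_in_dry": 1000.0,   # pmol mol-1
    "h2o_in": 15.0,         # mmol mol-1
    "g_bw": 2.44,           # mol m-2 s-1
    "g_sw": 0.6,            # mol m-2 s-1
    "t_leaf": 25.0,         # degC
}


def error_stats(est, obs):
    """(RMSE, MBE) of an estimate series against observations.

    MBE = mean(est - obs) signs the bias; RMSE = sqrt(mean((est - obs)^2))
    >= |MBE| always, with equality iff the residual is constant.
    """
    est = np.asarray(est, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if est.shape != obs.shape or est.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    d = est - obs
    return float(np.sqrt(np.mean(d * d))), float(np.mean(d))


@dataclass
class PosteriorEnsemble:
    """Optimized states from Monte Carlo replicate inversions.

    members : (n_members, n_state) array of packed posterior states.
    covariance : sample covariance over members (ddof=1); its diagonal is
        the member variances.
    n_failed : replicates dropped for non-convergence.
    """

    members: np.ndarray
    names: list
    n_failed: int = 0

    @property
    def member_count(self) -> int:
        return len(self.members)

    @property
    def mean(self) -> np.ndarray:
        return self.members.mean(axis=0)

    @property
    def covariance(self) -> np.ndarray:
        if len(self.members) < 2:
            return np.zeros((self.members.shape[1],) * 2)
        return np.cov(self.members, rowvar=False, ddof=1)

    @property
    def sigma(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.names)

    def correlation(self) -> pd.DataFrame:
        cov = self.covariance
        sd = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sd, sd)
        return pd.DataFrame(corr, index=self.names, columns=self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.members, columns=self.names)


def monte_carlo_posterior(model, n_members: int = 200, seed: int = 0,
                          perturb_prior: bool = True, perturb_obs: bool = True,
                          maxiter: int = 500) -> PosteriorEnsemble:
    """Monte Carlo posterior ensemble of re-optimized states.

    Each member draws independent Gaussian noise for every prior mean
    (within the prior sigma, truncated to the optimizer bounds) and for
    every observation of every point (within the per-point observational
    sigma; drawn independently per point and per member), then re-runs the
    full bounded optimization from the perturbed prior.  Seeded and
    bit-reproducible.  Non-converged members are recorded and excluded.
    """
    from .inversion import CuvetteInversion, PriorSpec

    if n_members < 1:
        raise ValueError("need at least one member")
    rng = np.random.default_rng(seed)
    prior = model.prior
    x_prior = prior.mean.pack()
    s_prior = prior.sigma.pack()
    bounds = np.array(prior.mean.bounds(), dtype=float)
    members, n_failed = [], 0
    for _ in range(n_members):
        x0 = x_prior.copy()
        if perturb_prior:
            x0 = x_prior + s_prior * rng.standard_normal(len(x_prior))
            x0 = np.clip(x0, bounds[:, 0], bounds[:, 1])
        data = model.data.copy()
        if perturb_obs:
            for col, sig in (("cos_out_dry", "sigma_cos"),
                             ("co2_out_dry", "sigma_co2"),
                             ("h2o_out", "sigma_h2o")):
                data[col] = data[col] + data[sig] * rng.standard_normal(len(data))
        pm = prior.mean.unpack(x0)
        member_model = CuvetteInversion(
            data, prior=PriorSpec(mean=pm, sigma=prior.sigma),
            weights=model.weights, gamma_variant=model.gamma_variant,
            g_mw=model.g_mw, co2_constants=model.co2_constants,
        )
        res = member_model.fit(maxiter=maxiter)
        if res.converged:
            members.append(res.params.pack())
        else:
            n_failed += 1
    if not members:
        raise RuntimeError("no Monte Carlo member converged")
    return PosteriorEnsemble(members=np.array(members),
                             names=prior.mean.names, n_failed=n_failed)


@dataclass
class ForwardSpread:
    """Output spread of perturbed forward simulations at one chamber
    condition."""

    draw_count: int
    discarded_count: int
    mean: pd.Series
    std: pd.Series
    draws: pd.DataFrame


def _draw_parameters(mean, cov, n_draws, rng):
    dim = len(mean)
    if not np.any(cov):
        return np.tile(mean, (n_draws, 1))
    jitter = 1e-12 * max(np.trace(cov) / max(dim, 1), 1.0)
    for _ in range(3):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(dim))
            break
        except np.linalg.LinAlgError:
            jitter *= 1e3
    else:
        raise np.linalg.LinAlgError("covariance not positive definite even with jitter")
    z = rng.standard_normal((n_draws, dim))
    return mean + z @ chol.T


def forward_spread(mean, covariance, names, variant: str,
                   condition: Optional[dict] = None, plant=None,
                   n_draws: int = 500, seed: int = 0, g_mw: float = 10.0,
                   co2_constants=None) -> ForwardSpread:
    """Propagate parameter uncertainty through the forward model.

    Draws ``n_draws`` correlated Gaussian parameter vectors from
    (mean, covariance) - typically a :class:`PosteriorEnsemble`'s moments,
    or a diagonal prior covariance - discards every draw in which any
    parameter lies more than three standard deviations from the mean, runs
    the forward simulation at the given chamber ``condition`` for each
    surviving draw, and reports the mean and standard deviation of the
    simulated outflows, fluxes and LRU.

    ``plant`` selects which per-plant V_max entries drive the simulation
    (default: the first plant in ``names``).
    """
    from .kinetics import CO2Constants

    cond = dict(CANONICAL_CONDITION)
    if condition:
        cond.update(condition)
    mean = np.asarray(mean, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    rng = np.random.default_rng(seed)
    draws = _draw_parameters(mean, covariance, n_draws, rng)
    sd = np.sqrt(np.diag(covariance))
    ok = np.ones(len(draws), dtype=bool)
    positive = sd > 0
    if positive.any():
        dev = np.abs(draws[:, positive] - mean[positive]) / sd[positive]
        ok &= (dev <= 3.0).all(axis=1)
    kept = draws[ok]
    discarded = int(len(draws) - len(kept))
    if len(kept) == 0:
        raise RuntimeError("all draws were discarded by the 3-sigma trim")

    idx = {n: i for i, n in enumerate(names)}
    plant_ids = [n[len("v_max_ca["):-1] for n in names if n.startswith("v_max_ca[")]
    if not plant_ids:
        raise ValueError("state names carry no per-plant V_max entries")
    p = str(plant) if plant is not None else plant_ids[0]
    if p not in plant_ids:
        raise ValueError(f"unknown plant {plant!r}; have {plant_ids}")

    def col(name):
        return np.clip(kept[:, idx[name]], 1e-9, None)

    v_ca = col(f"v_max_ca[{p}]")
    v_rub = col(f"v_max_rub[{p}]")
    t_eq = np.clip(kept[:, idx["t_eq_ca"]], 1.0, 60.0)
    dh_rub = col("dH_a_rub") * 1000.0
    if variant == "S1":
        gspec = GammaCosSpec.s1()
    elif variant == "S2":
        gspec = GammaCosSpec.s2(m_cos=col("m_cos"))
    elif variant == "S3":
        gspec = GammaCosSpec.s3(dH_a_gamma=col("dH_a_gamma") * 1000.0)
    else:
        gspec = GammaCosSpec.s4(dH_a_gamma=col("dH_a_gamma") * 1000.0)
    leaf = LeafParameters(
        g_sw=cond["g_sw"], g_mw=g_mw,
        ca=CAKinetics(v_max_ca=v_ca, t_eq_ca=t_eq),
        rub=RubiscoKinetics(v_max_rub=v_rub, dH_a_rub=dh_rub),
        co2c=co2_constants if co2_constants is not None else CO2Constants(),
        gamma=gspec,
    )
    cfg = ChamberConfig(af=cond["af"], s=cond["s"], p_air=cond["p_air"],
                        g_bw=cond["g_bw"])
    sim = forward_simulate(cfg, leaf, cond["cos_in_dry"], cond["co2_in_dry"],
                           cond["h2o_in"], cond["t_leaf"])
    outputs = pd.DataFrame({
        "cos_out_dry": np.broadcast_to(sim.cos_out_dry, (len(kept),)),
        "co2_out_dry": np.broadcast_to(sim.co2_out_dry, (len(kept),)),
        "h2o_out": np.broadcast_to(sim.h2o_out, (len(kept),)),
        "f_cos": np.broadcast_to(sim.f_cos, (len(kept),)),
        "f_co2": np.broadcast_to(sim.f_co2, (len(kept),)),
        "lru": np.broadcast_to(sim.diagnostics.lru, (len(kept),)),
    })
    return ForwardSpread(
        draw_count=n_draws, discarded_count=discarded,
        mean=outputs.mean(), std=outputs.std(ddof=1), draws=outputs,
    )
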