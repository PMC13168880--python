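# Methods

`leafcos` models the steady-state exchange of carbonyl sulfide (COS), CO₂
and water vapour between a leaf and a flow-through cuvette, and inverts
that model for the leaf's physiological state from per-interval
measurements of the inflowing and outflowing mole fractions.  This note
records the model equations, the estimation machinery, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## The chamber–leaf model

Four well-mixed layers are chained in series: cuvette air (a), leaf
boundary layer (b), intercellular airspace (i), and the mesophyll surface
(c).  At steady state the balance for each gas reads

    (AF/S)([gas]_in − [gas]_a) = g_b([gas]_a − [gas]_b)
                               = stomatal term
                               = mesophyll term,

with AF the molar air flow (mol s⁻¹), S the leaf area (m²), and g_b, g_s,
g_m the boundary, stomatal and mesophyll conductances (mol m⁻² s⁻¹).  The
accumulation terms vanish at steady state, so the cuvette volume and the
molar volume drop out of every result (asserted by a perturbation test).
For the trace gases the stomatal term carries a ternary correction for the
bulk outflow of transpired water:

    g_s([gas]_b − [gas]_i) − E([gas]_b + [gas]_i)/2,

with E the transpiration in mol m⁻² s⁻¹.  The boundary-layer ternary term
scales with E/g_bw and is negligible at the large fan-driven g_bw of a
cuvette; it is omitted.  Species conductances scale from the water-vapour
values by fixed diffusivity ratios (g_s/1.6 and g_b/1.4 for CO₂, g_s/1.94
and g_b/1.56 for COS).

The mesophyll closure differs per gas:

* **H₂O** — the mesophyll surface is saturated ([H₂O]_c from the
  Magnus-type saturation pressure and air pressure); a large mesophyll
  conductance g_mw = 10 mol m⁻² s⁻¹ lets the intercellular relative
  humidity RH_i sit slightly below 100 %.  The chain is four resistors in
  series and solves in closed form.
* **COS** — the sink is g_m,COS(T)·([COS]_i − Γ_COS(T)).  g_m,COS is the
  carbonic-anhydrase (CA) conductance: an Arrhenius rise (activation
  energy 40 kJ mol⁻¹) damped by an activation→inactivation equilibrium
  (enthalpy 100 kJ mol⁻¹) peaked near the optimum temperature T_eq,CA, and
  normalized so g_m,COS(T_eq,CA) = V_max,CA exactly.  The temperature
  terms of the equilibrium factor are taken in Kelvin throughout; the
  normalization makes any affine rescaling of that choice observationally
  equivalent.  The whole system stays linear and solves in closed form, so
  mass-balance residuals are at machine precision.
* **CO₂** — the sink is the enzyme-limited assimilation minus dark
  respiration, A_m(p_i) − R_d(T), with A_m = V_max,Rub·f_Rub(T)·(p_i −
  Γ*)/(p_i + K_c(1 + p[O₂]_i/K_o)).  Light- and export-limited branches
  are not modelled: the experiments the package emulates ran at saturating
  light, where the enzyme-limited branch is the binding one.  Γ* =
  p[O₂]_i/(2τ) with the specificity τ Q10-scaled (0.57) from 298 K; K_c,
  K_o and R_d are Q10-scaled from their 298 K table values.  Because A_m
  is a rational function of p_i and the diffusive supply is affine in x_i,
  the steady state is the positive root of a quadratic; it is evaluated in
  the numerically stable closed form (one positive root exists for any
  admissible parameters, by the sign of the constant coefficient).

Mole fractions are wet-air basis inside the model (pmol/µmol/mmol mol⁻¹
for COS/CO₂/H₂O); conversion to the dry-air measurement basis
(x_dry = x_wet/(1 − [H₂O]/1000)) happens only at the I/O boundary.  The
small increase of the outlet molar flow by transpiration (< 3 %) is
neglected consistently, in flux computation and model alike.  Fluxes are
uptake-positive.

Four temperature functions of the COS compensation point are supported:
S1 ≡ 0; S2 linear, m_COS(T − T_ref) with T_ref = 16.4 °C; S3/S4 Arrhenius
around a measured anchor (55.0 pmol mol⁻¹ at 293 K, resp. 138.7 pmol mol⁻¹
at 298 K) with activation energy ΔH_a,Γ.  All variants are clamped at zero
from below (a compensation point is a mole fraction).  Inverting the
Arrhenius form through the two printed anchors, taken literally at 293 and
298 K, gives the 134.3 kJ mol⁻¹ starting value; using 292.95/298.15 K
instead does not reproduce that printed figure, which is why the anchors
default to the integer-Kelvin values.

## Compensation-point estimation

**Regression route.**  In a concentration-ramp experiment the net COS flux
is exactly linear in the outflowing mole fraction (the chamber system is
linear in the inflow), so Γ_COS is the x-intercept of an ordinary
least-squares line, −β₀/β₁.  Its 95 % CI comes from the delta method on
the coefficient covariance with a t quantile at n−2 degrees of freedom;
Fieller's exact ratio interval is available behind a flag (`method=
"fieller"`) and agrees closely whenever the slope is well resolved.
Residual empty-chamber background variability widens the interval by
adding σ_f² + (β₁σ_c)² to the per-point variance (flux and concentration
residuals respectively); the widened interval is never narrower than the
original.

**Indirect route.**  With optimized parameters, the layer balances invert
algebraically from the measured in/out mole fractions down to [COS]_c,
which at steady state is the compensation point itself.  The transpiration
used in the ternary terms comes from the H₂O model with the optimized
stomatal conductance and the observed inflow humidity — not the measured
outflow — so the inversion is self-consistent with the optimized state.
Applied to noise-free forward-model output the round trip returns
Γ_COS(T) to better than 1e-8 relative; this identity is the package's
central correctness oracle.  One transcription note: consistency requires
the ternary term of the final rearrangement to carry the factor 1/2
(F_H₂O/(2g_m))([COS]_b + [COS]_i); the package uses the algebraically
consistent form.

## State inversion

The state vector holds per-plant V_max,CA and V_max,Rub, shared T_eq,CA,
compensation-point parameter (m_COS or ΔH_a,Γ, absent for S1) and
ΔH_a,Rub, and one stomatal conductance per data point.  The cost is

    J_tot = J_bg + J_COS + J_CO₂ + J_H₂O,

where J_bg = Σ(x−x_a)²/(W_bg σ²) penalizes departure from the prior and
each observational term sums ([gas]_out,est − [gas]_out,obs)²/(W σ²) over
points, on the dry-air basis using the observed outflow humidity.  The
weights sit in the denominator next to σ²: a larger weight *down-weights*
a gas.  They exist because the CO₂ record is two orders of magnitude more
precise than the others and would otherwise monopolize the fit; the
default set (W_COS = 0.034, W_CO₂ = 7.2, W_H₂O = 3.24, W_bg = 1)
corresponds to prior reduced-cost targets of 30/100/3, and
`select_weights` reproduces any such target from the unweighted prior
χ² = J/n.  A full candidate-grid refit search is intentionally not run by
default — the fixed set above is used — since re-optimizing per candidate
is expensive and the selection rule involves a judgement call (whether the
averaged observational cost-reduction rates are to be minimized, as
worded, or maximized; both readings are selectable by the user looping
over `WeightSet` candidates).

Minimization is bounded SLSQP from the prior mean (bounds: V_max,CA
[0.01, 0.5] mol m⁻² s⁻¹, V_max,Rub [1, 200] µmol m⁻² s⁻¹, T_eq,CA [1, 60]
°C, compensation parameter [1, 300], ΔH_a,Rub [1, 100] kJ mol⁻¹, g_sw
[0, 3] mol m⁻² s⁻¹; function tolerance 1e-10, 500 iterations).  ΔH values
travel in kJ mol⁻¹ inside the state so all entries have comparable
magnitude for the finite-difference gradients.  Two numerical guards: the
g_sw lower bound is a closed stomate where the conductance chain is
singular, so the forward mapping floors g_sw at 1e-9 (the fluxes have a
well-defined zero limit); and a cost of (numerically) zero is accepted as
converged regardless of the optimizer's exit status, because every cost
term is non-negative, making zero a certificate of global optimality —
SLSQP spuriously reports "inequality constraints incompatible" when
started exactly at such a point.  On any other reported failure the fit
polishes once from the best iterate before giving up; non-convergence is
reported on the results object with the best iterate.

Priors: V_max,CA 0.125 ± 0.060 mol m⁻² s⁻¹ and V_max,Rub 90 ± 20 µmol m⁻²
s⁻¹ per plant, T_eq,CA 30 ± 15 °C, m_COS 16.2 ± 16.2 pmol mol⁻¹ K⁻¹ (the
Arrhenius variants use ΔH_a,Γ 134.3 kJ mol⁻¹ with the same 100 % relative
σ, since a separate printed value exists only for the linear variant),
ΔH_a,Rub 60 ± 12 kJ mol⁻¹, and per-point g_sw at its measured value with
σ = sqrt(0.08² + 0.02² + (g_sw·σ_H₂O/[H₂O]_out)²) — run-to-run
variability, instrument allowance, and the normalized per-point H₂O
measurement error; the composition rule (root-sum-square) is this
package's choice where only the three contributions are stated.

## Uncertainty

Posterior uncertainty comes from a randomize-then-optimize Monte Carlo:
each ensemble member adds independent Gaussian noise to every prior mean
(within the prior σ, truncated to the optimizer bounds — truncation
rather than resampling keeps the draw count deterministic) and to every
observation of every point (within its own σ, drawn independently per
point and per member), then re-runs the full bounded optimization from
the perturbed prior.  The member spread and covariance are the posterior
σ and covariance; non-converged members are excluded and counted.  The
study-scale member count is 200.

Forward uncertainty at a reference chamber condition (103 100 Pa, AF
3.5·10⁻⁴ mol s⁻¹, [CO₂]_in 400 µmol mol⁻¹, [COS]_in 1000 pmol mol⁻¹,
[H₂O]_in 15 mmol mol⁻¹, g_bw 2.44, g_sw 0.6, 25 °C) propagates correlated
Gaussian parameter draws (ensemble mean and covariance; a Cholesky factor
with a jitter of 1e-12 of the mean diagonal if the covariance is
semidefinite) through the forward model.  A draw is discarded when *any*
component lies more than three standard deviations from the mean — the
conservative per-component reading; for a single uncertain parameter this
trims the 0.27 % Gaussian tail mass.  Model skill is summarized by
RMSE, the signed mean bias MBE (RMSE ≥ |MBE| always), and the reduced
cost χ² = J/n per part, which includes the weights exactly as the cost
does.

A known behaviour worth stating: the posterior σ of individual per-point
g_sw entries does not always drop below the prior σ.  At wide stomatal
opening the H₂O outflow saturates in g_sw (the intercellular air is
already near chamber humidity), so those entries stay prior-dominated;
the g_sw block shrinks on average, and every physiological entry shrinks
individually.

## Synthetic data

The generator emulates the three cuvette experiment designs: a COS
concentration ramp (inflow 94–707 pmol mol⁻¹, four levels) at a fixed
temperature; a stomatal sweep (g_sw 0.3–1.1 mol m⁻² s⁻¹, eight levels) at
≈25 °C and elevated COS (≈900–1200 pmol mol⁻¹); and a temperature sweep
(19.0–30.9 °C, twelve levels) at g_sw ≈ 0.6.  The default campaign is
three plants swept in g_sw and two of them in temperature — 48 points.
Independent Gaussian noise is added per gas to the outflow record with
σ_COS = 16.7 pmol mol⁻¹, σ_CO₂ = 0.2 µmol mol⁻¹, σ_H₂O = 0.3 mmol mol⁻¹
(the campaign-average 150-s interval standard deviations), and the
reported g_sw carries a 0.02 mol m⁻² s⁻¹ instrument-scale error.  A
temperature-dependent COS emission from the chamber material
(0.15·T + 0.05 pmol m⁻² s⁻¹, chosen once so the emission is ≈6–7 % of a
typical mid-range leaf flux — the empty-chamber fit itself prints no
coefficients) is injected as a source that raises the apparent outflow;
`apply_emission_correction`/`correct_chamber_flux` remove it exactly when
the residual scatter is off, mirroring the observational preprocessing of
a real campaign.  Generating-truth physiology defaults to the posterior
state values (V_max,CA 0.217 mol m⁻² s⁻¹, T_eq,CA 39.7 °C, m_COS 22.4
pmol mol⁻¹ K⁻¹, V_max,Rub 94.4 µmol m⁻² s⁻¹, ΔH_a,Rub 54.5 kJ mol⁻¹),
with optional 10 % lognormal per-plant jitter of the two capacities,
deterministic in the plant id.  A dew-point condensation filter is not
simulated (synthetic chambers never condense); instrument drift and
calibration cycles are likewise out of scope.

What passing tests on these data do and do not show: the generator shares
its forward model with the estimator, so recovery tests certify the
estimation machinery (identifiability, calibration of the noise
propagation, absence of coding errors), not the model's adequacy for real
leaves — there is no structural model error, no drift, and the noise is
exactly Gaussian and independent.  One consequence observed at study
scale: the synthetic campaign constrains the compensation-point slope
*more* tightly than model-error-bearing real data would, so the Monte
Carlo posterior σ of m_COS (≈3.4 at 200 members) closely matches the
replicate-to-replicate spread of the point estimate instead of exceeding
it (the CA optimum temperature sits above the swept range and is weakly
identified, and its strong positive correlation with m_COS lets noise
excursions carry the slope with it).  The package's recovery-coverage
test therefore checks nominal 1σ coverage honestly and is expected to sit
near the Gaussian ≈68–80 % rather than above 90 %; see the test itself
for the exact protocol (50 replicates, posterior σ from a 32-member
ensemble, stated problem sizes chosen to keep the full study cheap on one
CPU).

## Problem sizes used by tests and scripts

Unit tests run single solves and small (10–12 point) inversions; the
campaign-scale checks use the full 48-point suite.  Monte Carlo tests use
16-member ensembles (32 for the coverage study); forward-spread tests use
50–20 000 draws depending on what is being measured.  The acceptance
script's reported quantity (intercellular relative humidity at the
reference condition) is a deterministic single solve.
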