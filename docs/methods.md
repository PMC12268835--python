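# Methods

## Model structure and assumptions

The model tracks seven carbon pools in a bulk soil layer: metabolic and
structural litter, two microbial functional groups (copiotrophic MIC_r,
favouring labile substrate with high maximum uptake and lower substrate
affinity; oligotrophic MIC_k, the converse), and three soil organic matter
pools (physically protected, chemically protected, available). All pools
are in mgC cm⁻³ and all rates per hour. Forcing is constant within a day.

Litter inputs split between the metabolic and structural pools by the
metabolic fraction `f_met = clip(f_met0 − f_met_slope · lignin:N, 0.01,
0.99)` with defaults 0.85 and 0.013; a small fraction `f_i` (0.05)
bypasses litter and enters the protected SOM pools directly. Uptake of
substrate S by group M is reverse Michaelis–Menten,
`MIC · Vmax(T) · S/(Km(T)+S) · θ`, with `Vmax = exp(v_slope·T + v_int) ·
a_v · vMOD · vmax_scale` and `Km = exp(k_slope·T + k_int) · a_k / kMOD`.
The soil-moisture scalar θ multiplies **all** microbial fluxes, including
available-SOM uptake and the oxidation of chemically protected SOM; a
config flag (`moisture_on_som`) restricts it to litter fluxes if wanted.
`vmax_scale = 0.6` in the default configuration — catabolic capacity is
reduced by 40% so that the starting kinetics agree with field-scale litter
decomposition before any calibration; calibration is then free to adjust
drivers rather than correct a kinetics bias.

Assimilated carbon is `CUE · flux`; the remainder is respired. The
derivative assembly guarantees d(total C)/dt = inputs − respiration
exactly (verified to 1e-10 relative over random states).

Microbial turnover is density dependent: `MIC^β · τ · f_S` with β = 1.5.
β > 1 penalises high biomass, damps the predator-prey-like oscillations
microbially explicit models are prone to, and guarantees both groups
persist at (possibly tiny) positive abundance; a viability floor of
1e-6 mgC cm⁻³ defines whether a group counts as ecologically "viable".
τ increases with litter quality (`τ = τ_base · exp(τ_mod · f_met)`,
τ_mod 0.3 copiotrophs / 0.1 oligotrophs). Turnover is partitioned among
SOM pools by fixed fractions `f_S` per group. In the wider model family
these fractions vary with clay and litter quality; here they are constants
(editable in the parameter file) because the litterbag overlay — the
quantity of interest — is insensitive to SOM partitioning except through
steady-state microbial biomass. Chemically protected SOM is oxidised back
to available SOM by microbial activity (a transfer without respiration);
without that pathway the chemically protected pool has no loss term and no
steady state exists. Physically protected SOM desorbs at
`d_base · exp(−d_clay · clay)`.

Parameters not constrained by the analysis (temperature responses, CUE,
τ_base, partitioning, desorption) take canonical values for this model
family and live in one YAML file so an alternative configuration can be
substituted verbatim.

## Units bridge

Annual litterfall (gC m⁻² yr⁻¹) becomes a volumetric input over a 30 cm
bulk-soil depth: `I = litterfall · 0.1 / 30 / 8760` mgC cm⁻³ hr⁻¹. 30 cm
is the conventional bulk depth for this model family and yields both
realistic standing stocks (≈ 5–8 kgC m⁻² total SOM at the packaged sites)
and field-scale litterbag decay (site-mean mass loss ≈ 35–55% at 10
months, 55–75% at 21 months). The depth is exposed in the parameter file.

## Steady states

Steady states are always reached by spin-up: forward integration for 60
years from one standard initial state, followed by a root polish
(`scipy.optimize.root`, hybr) in log-pool space (which enforces
positivity), followed by a local-stability check on the numerical
Jacobian. If the polished root is unstable or the residual exceeds 1e-8
relative to the litter input rate, a 500-year integration fallback runs
before an error is raised. Integrating *before* rooting matters: the
system can have multiple equilibria (and saddles the root-finder would
happily land on), so the basin of attraction from the standard initial
state — not the caller's history — selects the reported state, making
results independent of evaluation order. The spin-up uses a numba-compiled
Dormand–Prince stepper when numba is importable and scipy's LSODA
otherwise; a unit test pins both to the reference derivative function.

## Litterbags

Bags are two overlay pools initialised to `f_met` and `1 − f_met` of an
initial carbon density `bag_c0` (1.25 mgC cm⁻³, roughly a 5 g bag over
20 × 20 cm and the bulk depth; it matters only through Michaelis–Menten
saturation). Each day after deployment (day-of-year 315) the bag pools are
decomposed by the *fixed* steady-state microbial biomass under that day's
temperature and moisture; everything removed leaves the system — the
respired/assimilated split is irrelevant to bag mass. Percent mass
remaining is taken equal to percent carbon remaining. Daily steps use one
classical RK4 stage per pool per day (error vs a refined-step integration
< 0.1% mass remaining over three years). Collections at 10 and 21 months
use 30.42 days per month, i.e. days 304 and 639 after deployment.

## Effect sizes

Percent mass loss (both collections pooled, no time fixed effect) is
regressed on standardized log soil moisture, lignin:N and
copiotroph:oligotroph ratio with random intercepts for site and plot
within site, by REML (`statsmodels MixedLM`). The optimizer runs Powell
first — the plot variance component is weakly identified with two
observations per plot and gradient methods routinely stall — and the
fixed-effect covariance is computed from the GLS identity (X'V⁻¹X)⁻¹ at
the fitted variance components, which remains defined when a variance sits
on the boundary. A singular or failed nested fit falls back to a site-only
random intercept with a logged warning. Coefficients are relativized to
signed percentages, `100 · b_i / Σ|b_j|`, over the three fixed effects
only; the intercept is excluded so absolute values total exactly 100.
Standardization is within-table (model-output and observational tables
are standardized separately). VIFs come from OLS R² of each predictor on
the others; < 5 is taken as acceptable. For model-output tables, "plot" is
each litter × moisture-variant combination, moisture is the temporally
averaged daily scalar, and the community predictor is steady-state
MIC_r:MIC_k, capped at 10³ where the oligotroph pool is vanishingly small.

## Calibration

Four multipliers are drawn independently and uniformly within their ranges
(τ_r 0.3–2, β 0.67–1.33, metabolic and structural Vmax modifiers 0.5–2,
applied identically to both microbial groups). Each draw runs the full
63-run design; screening keeps a draw iff (1) every site-mean simulated
mass loss falls inside the observed per-site min–max envelope at both
collections, (2) all three relative effect sizes are within 10 points of
the observed ones (a per-driver tolerance vector is accepted), (3) RMSE
over the 14 site × collection means is below 5.4 %, and (4) every run
keeps at least one viable microbial group. Survivors are ranked by RMSE
with ties broken by summed absolute effect-size deviation — decomposition
fit is deliberately prioritised over effect-size fit — and the top three
form the calibrated model. A leave-10%-out stability check refilters
random 90% subsets of the evaluated runs and reports selection overlap.

Because a draw's simulations do not depend on the observations, records
are evaluated once and re-screened cheaply. The closed-loop recovery
experiment exploits this: a pool of draws is evaluated once, and each
repetition regenerates noisy synthetic observations from a known truth
set (mass-loss noise 1.5 percentage points, log-normal ratio noise 10%)
and screens a seeded 500-draw subsample.

**Identifiability.** Mass loss at 10/21 months identifies the structural
Vmax multiplier strongly but the turnover, density and metabolic-rate
multipliers only weakly — metabolic litter is largely exhausted by the
first collection under any admissible rate — so well-separated multiplier
sets can satisfy all four screens (equifinality). Recovery of a known set
to within 15% in *all four* multipliers simultaneously therefore fails in
most repetitions even though the selected sets reproduce the truth's
observable behaviour; the recovery test reports the measured fraction.

## Climate experiment

Monthly anomalies (temperature delta, additive moisture delta clipped to
keep the scalar in [0, 1], multiplicative litterfall factor) are added to
the historical daily climatology for a 2072–2074 window; the three
adjusted years are averaged back into one climatology so the steady-state
and litterbag machinery runs unchanged, and future steady states are
solved from the future annual means. The synthetic anomaly generator ramps
linearly from a 2022 baseline to defaults of +3 °C (winter-amplified by
±1 °C), −0.03 moisture (summer-amplified), and +10% litterfall —
magnitudes typical of a high-emissions scenario at these latitudes by the
2070s. The climate response of a run is future-minus-historical mass loss
per collection; the calibration effect is
`100 · (Δ_cal − Δ_def)/|Δ_def|`, with runs where |Δ_def| < 0.1 percentage
points reported as absolute differences and flagged. The driver analysis
fits the 126-row response table with plot-in-site random intercepts on
site clay, site moisture variability (max-minus-min moisture multiplier),
plot lignin:N, and litterfall / soil temperature / (log) soil moisture in
historical, future, or delta form; predictors are standardized within
table. An exactly constant response short-circuits to zero coefficients
(the mixed model is unidentified there).

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not the physics of any land-surface model:

- **Daily climatologies** — seasonal cosine plus smoothed seeded noise,
  rescaled so annual mean and SD match the site table exactly (moisture is
  then clipped to [0, 1]); litterfall is an autumn Gaussian pulse over a
  10% baseline, normalised to the annual total.
- **Field observations** — per-plot log-normal moisture and ratio,
  site-anchored lignin:N, and mass loss built from the stated effect
  structure (moisture +5, lignin:N −3, C:O −4 percentage points per SD)
  plus site (SD 3), plot (SD 2) and residual (SD 4) noise, two collections
  per plot, 62 plots over 7 sites (124 rows) by default.
- **ASV tables** — Dirichlet-multinomial counts with known
  copiotroph/oligotroph/unassigned labels and emitted true ratios.
- **Model observations** — the 63-run design under a reference multiplier
  set plus seeded noise, with per-site min/mean/max envelopes, making the
  calibration demonstration self-consistent.

Passing tests on these generators shows the machinery recovers known
structure at realistic noise; it does not validate the model against real
field or sequence data, which differ in autocorrelation, measurement
error, and community composition.

## Numerical choices and limitations

Steady-state tolerance 1e-8 (relative to the input rate); stability
threshold Re(λ) < 1e-9 hr⁻¹; RK45 spin-up tolerances rtol 1e-5 /
atol 1e-10; litterbag RK4 at one step per day; ratio cap 10³; viability
floor 1e-6 mgC cm⁻³. Zero litterfall returns the all-zero steady state.
Rarefaction uses exact multivariate hypergeometric draws; samples below
the 2447-read depth are flagged and dropped. Same-rank conflicting
classification rules are dropped to unassigned with a warning. Problem
sizes in the shipped tests and acceptance script (500-draw screens from a
1000–2000 draw pool, 200 effect-size replicates, 60-year spin-ups) are
desk-scale choices that keep the full suite reproducible on one CPU.

Not represented: nitrogen, multi-layer soil, fungal communities,
mesofauna, leaching or fragmentation, within-bag succession, and coupling
to any land-surface or Earth-system model.
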