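# mimicslite

A microbially explicit litter and soil carbon model for temperate forest
sites, with a litterbag decomposition simulator, a 16S copiotroph:oligotroph
microbiome stage, mixed-effects effect-size estimation, Monte Carlo
calibration of kinetic parameters against decomposition rates *and* their
empirical drivers, and an anomaly-forced climate-change experiment.

## Who this is for

Soil ecologists and ecosystem modellers who want to confront a
microbially explicit decomposition model with field litterbag data — not
just matching mass-loss curves, but matching the *effect sizes* of the
drivers (soil moisture, litter quality, microbial community composition)
that a mixed-effects analysis of the field data recovers.

## The model

Seven pools (mgC cm⁻³): metabolic and structural litter (LIT_m, LIT_s),
copiotrophic and oligotrophic microbial biomass (MIC_r, MIC_k), and
physically protected, chemically protected and available soil organic
matter (SOM_p, SOM_c, SOM_a). Litter inputs are split by the metabolic
fraction f_met = clip(0.85 − 0.013·lignin:N, 0.01, 0.99). Microbial uptake
of each substrate S follows reverse Michaelis–Menten kinetics,

    F = MIC · V_max(T) · S / (K_m(T) + S) · θ,

with V_max and K_m exponential in temperature T, θ the 0–1 soil-moisture
scalar, and a global 0.6 scaling of V_max (a 40% reduction of catabolic
capacity) in the default configuration. A fraction CUE of uptake is
assimilated, the rest respired; carbon balance is exact by construction.
Microbial turnover is density dependent,

    MIC_trn = MIC^β · τ · f_S,    β = 1.5 by default,

partitioned among the SOM pools by f_S. Protected SOM returns to the
available pool by clay-dependent desorption and microbial oxidation.
Litterbags are overlay pools decomposed by the steady-state microbial
biomass with no feedback; bags deploy on day-of-year 315 and are scored
after 10 and 21 months.

Four parameters are calibratable through multipliers — the litter-quality
coefficient on copiotrophic turnover τ_r (default 0.3, range 0.3–2), the
density exponent β (1.5, range 0.67–1.33), and the metabolic and structural
V_max modifiers (10/3 and 2/3 for the two microbial groups, ranges 0.5–2).
A 5000-draw (desk-scale: 500) uniform Monte Carlo screens each draw with
four criteria: site mass loss inside the observed min–max envelope,
relative effect sizes within 10 points of the observed ones, mass-loss
RMSE < 5.4%, and viable microbial groups; survivors are ranked by RMSE.

## Worked example

```python
from mimicslite import default_parameters, load_sites, steady_state
from mimicslite.litterbag import run_design
from mimicslite.effects import fit_mass_loss_model
from mimicslite.pipeline import daily_forcings_for

params = default_parameters()
sites = load_sites(role="calibration")          # 7 packaged forest sites
daily = daily_forcings_for(sites, seed=7)

tree = sites[0]                                  # coldest site
ss = steady_state(tree, "mean", 30.0, params)
print(round(ss.pools.mic_r, 3), round(ss.pools.mic_k, 3), round(ss.co_ratio, 2))
# 0.387 0.453 0.85

table = run_design(sites, daily, params)         # the 63-run design
print(table.groupby("timepoint")["mass_loss_pct"].mean().round(1).to_dict())
# {10: 47.9, 21: 66.2}

table["plot"] = table["site"] + "-" + table["litter_id"].astype(str) \
    + "-" + table["moisture_variant"]
print(fit_mass_loss_model(table).relative.round(1).to_dict())
# {'z_moisture': 50.8, 'z_lignin_n': -2.1, 'z_co_ratio': 47.2}
```

The steady state gives a copiotroph:oligotroph biomass ratio of 0.85 at
the coldest site; the 63 runs lose on average 47.9% of litter mass by 10
months and 66.2% by 21 months; and relativized to 100%, the default model
attributes litter mass loss mostly to soil moisture (+50.8) and the
copiotroph:oligotroph ratio (+47.2) with a weak litter-quality effect
(−2.1) — the positive community effect is exactly the kind of discrepancy
from field effect sizes that the calibration stage targets.

The same stages are scriptable from the shell:

```bash
mimicslite fixtures --out fx --seed 1
mimicslite litterbag --out results
mimicslite calibrate --out results --n-draws 500
mimicslite climate --out results
mimicslite classify --asv-table fx/synthetic_asv_table.tsv --rules fx/synthetic_rules.tsv
```

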