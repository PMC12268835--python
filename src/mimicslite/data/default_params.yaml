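# Default kinetic and stoichiometric constants for the seven-pool model.
#
# Units: pools in mgC cm^-3, time in hours, temperature in degC.
# Microbial groups: r = copiotrophic (MICr), k = oligotrophic (MICk).
# Substrates: m = metabolic litter, s = structural litter, a = available SOM.
#
# Every value here can be overridden from a user parameter file.

# Bulk-soil depth used to convert annual litterfall (gC m-2 yr-1) into a
# volumetric input rate (mgC cm-3 hr-1).
depth_cm: 30.0

# Global scaling of maximum catabolic rates; the default configuration runs
# with microbial catabolic capacity reduced by 40%.
vmax_scale: 0.6

# Exponential temperature response of Vmax: exp(v_slope*T + v_int) * a_v.
v_slope: 0.063
v_int: 5.47
a_v: 8.0e-6

# Flux-specific Vmax modifiers (per microbial group).
v_mod_m: {r: 10.0, k: 3.0}
v_mod_s: {r: 2.0, k: 3.0}
v_mod_a: {r: 10.0, k: 2.0}

# Half-saturation constants: Km = exp(k_slope*T + k_int) * a_k / k_mod.
k_slope: {m: 0.025, s: 0.035, a: 0.025}
k_int: 3.19
a_k: 10.0
k_mod_m: {r: 8.0, k: 2.0}
k_mod_s: {r: 2.0, k: 4.0}
k_mod_a: {r: 4.0, k: 6.0}

# Km amplifier for uptake/oxidation of protected and available SOM.
k_o: {r: 6.0, k: 6.0}

# Carbon-use efficiencies per microbe x substrate (assimilated fraction of
# uptake; the remainder is respired).
cue: {r_m: 0.55, r_s: 0.25, r_a: 0.55, k_m: 0.75, k_s: 0.35, k_a: 0.75}

# Microbial turnover: tau = tau_base * exp(tau_mod * fmet); biomass loss is
# MIC^beta * tau (density dependent for beta > 1).
tau_base: {r: 5.2e-4, k: 2.4e-4}
tau_mod_r: 0.3
tau_mod_k: 0.1
beta: 1.5

# Partitioning of microbial turnover among SOM pools (sums to 1 per microbe).
f_s:
  r: {som_p: 0.30, som_c: 0.10, som_a: 0.60}
  k: {som_p: 0.20, som_c: 0.20, som_a: 0.60}

# Fraction of litter inputs routed directly to SOM (metabolic -> physically
# protected, structural -> chemically protected).
f_i: {m: 0.05, s: 0.05}

# Desorption of physically protected SOM: rate = d_base * exp(-d_clay * clay).
d_base: 1.5e-5
d_clay: 1.5

# Metabolic fraction of litter inputs as a linear function of lignin:N,
# clipped to [0.01, 0.99].
f_met0: 0.85
f_met_slope: 0.013

# Whether the soil-moisture scalar multiplies SOM uptake/oxidation fluxes in
# addition to litter fluxes.
moisture_on_som: true

# Initial carbon density of a litterbag overlay (mgC cm-3); mass remaining is
# reported relative to this value so its magnitude only matters through the
# Michaelis-Menten saturation of bag substrate.
bag_c0: 1.25
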