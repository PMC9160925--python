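# Default dynamic and connectivity parameters of the packaged CBCT model.
#
# CLEARLY-MARKED DEFAULTS: none of the values in this file are published
# for the source model (per-pathway Gaussian kernels, weights, delays and
# bias-current moments were optimized against electrophysiology there and
# not printed).  These are this package's own documented defaults, chosen
# for sparse low-rate resting activity at desk scales.  Structural facts
# (region totals, layer lists, the ten inter-regional pathways, the 8 Hz
# mossy-fiber calibration target) live in cbct_composition.yaml and the
# builder, not here.

sheet_extent_mm: 1.0

neuron_defaults:
  exc: {tau_m: 10.0, C_m: 250.0, E_L: -70.0, V_th: -55.0, V_reset: -70.0, t_ref: 2.0}
  inh: {tau_m: 8.0, C_m: 200.0, E_L: -70.0, V_th: -55.0, V_reset: -70.0, t_ref: 1.5}

# bias currents (pA): normal(mean, sd) per population, drawn per neuron.
# GPe/GPi high-rate at rest; granule cells sparse; Pons purely drive-driven.
bias_currents:
  default: {mean: 250.0, sd: 120.0}
  cortex_exc: {mean: 280.0, sd: 120.0}
  cortex_inh: {mean: 230.0, sd: 100.0}
  MSN: {mean: 150.0, sd: 80.0}
  FSI: {mean: 230.0, sd: 80.0}
  GPe: {mean: 480.0, sd: 80.0}
  GPi_SNr: {mean: 480.0, sd: 80.0}
  STN: {mean: 420.0, sd: 80.0}
  TC: {mean: 280.0, sd: 100.0}
  IN: {mean: 220.0, sd: 80.0}
  RT: {mean: 220.0, sd: 80.0}
  granule: {mean: 150.0, sd: 100.0}
  golgi: {mean: 280.0, sd: 80.0}
  PC: {mean: 520.0, sd: 60.0}
  DCN: {mean: 350.0, sd: 80.0}
  stellate: {mean: 230.0, sd: 80.0}
  basket: {mean: 230.0, sd: 80.0}
  MF: {mean: 0.0, sd: 0.0}

# distance-dependent Gaussian connectivity classes (probability at zero
# distance p0, spatial scale sigma in mm, peak conductance in nS, delay ms)
gaussian_classes:
  cortex_EE: {p0: 0.10, sigma: 0.20, weight: 0.8, delay: 1.5, receptor: AMPA}
  cortex_EI: {p0: 0.20, sigma: 0.20, weight: 1.0, delay: 1.5, receptor: AMPA}
  cortex_IE: {p0: 0.30, sigma: 0.15, weight: 2.5, delay: 1.0, receptor: GABA_A}
  cortex_II: {p0: 0.25, sigma: 0.15, weight: 2.0, delay: 1.0, receptor: GABA_A}
  cortex_ff: {p0: 0.15, sigma: 0.15, weight: 1.0, delay: 1.5, receptor: AMPA}
  bg_inhib: {p0: 0.30, sigma: 0.30, weight: 2.0, delay: 1.5, receptor: GABA_A}
  bg_excit: {p0: 0.30, sigma: 0.30, weight: 1.0, delay: 1.5, receptor: NMDA}
  mf_granule: {p0: 0.20, sigma: 0.15, weight: 2.0, delay: 1.0, receptor: AMPA}
  mf_dcn: {p0: 0.30, sigma: 0.30, weight: 1.0, delay: 1.0, receptor: AMPA}
  pf_pc: {p0: 0.05, sigma: 0.25, weight: 0.3, delay: 1.5, receptor: AMPA}
  pf_interneuron: {p0: 0.05, sigma: 0.25, weight: 0.5, delay: 1.5, receptor: AMPA}
  granule_golgi: {p0: 0.10, sigma: 0.20, weight: 0.5, delay: 1.0, receptor: AMPA}
  golgi_granule: {p0: 0.20, sigma: 0.20, weight: 1.5, delay: 1.0, receptor: GABA_A}
  molecular_pc: {p0: 0.30, sigma: 0.15, weight: 1.5, delay: 1.0, receptor: GABA_A}
  pc_dcn: {p0: 0.40, sigma: 0.25, weight: 2.0, delay: 1.5, receptor: GABA_A}
  th_internal: {p0: 0.30, sigma: 0.25, weight: 1.0, delay: 1.0, receptor: GABA_A}
  th_tc_excite: {p0: 0.25, sigma: 0.25, weight: 1.0, delay: 1.0, receptor: AMPA}

# inter-regional topographic pathways: every post neuron links to its
# nearest presynaptic sheet coordinate, plus Gaussian-sampled spread
topographic: {p0: 0.25, sigma: 0.15, weight: 1.0, delay: 2.0}
relay_delay: 1.0       # parrot interface relay delay, ms

# Poisson drive of the Pons (mossy-fiber) population.  The rate was
# produced by calibrate_resting_input (bracketing bisection against the
# packaged Pons neuron, target 8 Hz resting rate) and persisted here.
pons_drive:
  weight: 2.0          # nS, AMPA
  rate: 419.921875     # Hz, calibrated to 8 Hz mossy-fiber resting rate
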