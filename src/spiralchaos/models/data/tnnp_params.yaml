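# ten Tusscher-Noble-Noble-Panfilov human ventricular model (2006 revision
# of the calcium dynamics), epicardial parameter set.
#
# Provenance: transcribed from the authors' description of the revised
# model (ten Tusscher & Panfilov 2006) as distributed by the CellML
# project ("ten_tusscher_model_2006_epi").  Units: mV, ms, mM, pA/pF,
# nS/pF; cell subvolumes in uL (so that concentration fluxes come out in
# mM/ms with currents in pA/pF and CAPACITANCE in uF).
#
# The "slope18" variant applies the published parameter changes that set
# the maximum APD-restitution slope to 1.8 and thereby enable spiral-wave
# breakup: G_Kr = 0.172, G_Ks = 0.441, G_pCa = 0.8666, G_pK = 0.00219 and
# the voltage-gated inactivation time constant tau_f doubled for V > 0 mV.
#
# Tissue-level overrides used by this package for 2-D simulations:
# Cm_tissue = 0.2e-2 uF/mm^2 and D = 1.54e2 mm^2/s (isotropic).
schema_version: 1
model: tnnp
default_variant: slope18
tissue:
  Cm_tissue_uF_per_mm2: 0.002
  D_mm2_per_s: 154.0
numerics:
  h_mm: 0.2
  dt_s: 2.0e-5
constants:
  R: 8314.472          # J / (kmol K)
  T: 310.0             # K
  F: 96485.3415        # C / mol
  Cm: 0.185            # uF (single-cell capacitance entering flux conversion)
  V_c: 0.016404        # cytoplasmic volume, uL
  V_sr: 0.001094       # sarcoplasmic-reticulum volume, uL
  V_ss: 0.00005468     # dyadic subspace volume, uL
  K_o: 5.4             # mM
  Na_o: 140.0          # mM
  Ca_o: 2.0            # mM
  G_Na: 14.838         # nS/pF
  G_K1: 5.405
  G_to: 0.294          # epicardial
  G_Kr: 0.153
  G_Ks: 0.392          # epicardial
  G_CaL: 3.98e-5       # cm^3 uF^-1 ms^-1
  G_bNa: 0.00029
  G_bCa: 0.000592
  G_pK: 0.0146
  G_pCa: 0.1238        # pA/pF
  K_pCa: 0.0005        # mM
  P_NaK: 2.724         # pA/pF
  K_mK: 1.0            # mM
  K_mNa: 40.0          # mM
  k_NaCa: 1000.0       # pA/pF
  gamma: 0.35
  K_mCa: 1.38          # mM
  K_mNai: 87.5         # mM
  k_sat: 0.1
  alpha: 2.5
  p_KNa: 0.03
  V_rel: 0.102         # mM/ms
  k1_prime: 0.15
  k2_prime: 0.045
  k3: 0.060
  k4: 0.005
  EC: 1.5              # mM, Ca_SR half-saturation of kcasr
  max_sr: 2.5
  min_sr: 1.0
  V_leak: 0.00036      # mM/ms
  V_xfer: 0.0038       # mM/ms
  Vmax_up: 0.006375    # mM/ms
  K_up: 0.00025        # mM
  Buf_c: 0.2           # mM
  K_buf_c: 0.001       # mM
  Buf_sr: 10.0         # mM
  K_buf_sr: 0.3        # mM
  Buf_ss: 0.4          # mM
  K_buf_ss: 0.00025    # mM
variants:
  baseline: {}
  slope18:
    G_Kr: 0.172
    G_Ks: 0.441
    G_pCa: 0.8666
    G_pK: 0.00219
    tau_f_mult_depol: 2.0
resting_state:
  # published epicardial initial conditions (near the 1 Hz paced steady state)
  V: -85.23
  m: 0.00172
  h: 0.7444
  j: 0.7045
  d: 3.373e-5
  f: 0.7888
  f2: 0.9755
  fCass: 0.9953
  r: 2.42e-8
  s: 0.999998
  xr1: 0.00621
  xr2: 0.4712
  xs: 0.0095
  Na_i: 8.604
  K_i: 136.89
  Ca_i: 0.000126
  Ca_SR: 3.64
  Ca_SS: 0.00036
  R_bar: 0.9073
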