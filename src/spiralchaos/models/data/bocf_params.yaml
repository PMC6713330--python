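# Bueno-Orovio–Cherry–Fenton minimal ventricular model: parameter sets.
#
# Provenance: transcribed from Table 1 of Bueno-Orovio, Cherry & Fenton,
# "Minimal model for human ventricular action potentials in tissue",
# J. Theor. Biol. 253 (2008) 544-560.  Time constants are given in
# MILLISECONDS here, exactly as printed in the source table; the loader
# converts them to seconds (the package-internal time unit).
# tau_winf is a dimensionless slope parameter despite its name and is not
# converted.
#
# The "TNNP" set tunes the minimal model to reproduce the dynamics of the
# ten Tusscher-Noble-Noble-Panfilov model and is the default set used for
# 2-D spiral-chaos simulations in this package.  EPI is shipped as an
# optional passthrough only.
schema_version: 1
model: bocf
time_unit: ms
default_set: TNNP
rescaling:
  V_rest_mV: -84.0      # resting membrane potential used in u = (Vm - Vrest)/(Vfi - Vrest)
  V_fi_mV: 1.7          # fast-inward Nernst level; Vfi - Vrest = 85.7 mV
diffusion:
  D_mm2_per_s: 200.0    # isotropic, tissue-level
numerics:
  h_mm: 1.0
  dt_s: 1.0e-4
sets:
  TNNP:
    u_o: 0.0
    u_u: 1.58
    theta_v: 0.3
    theta_w: 0.015
    theta_vminus: 0.015
    theta_o: 0.006
    tau_v1minus: 60.0
    tau_v2minus: 1150.0
    tau_vplus: 1.4506
    tau_w1minus: 70.0
    tau_w2minus: 20.0
    k_wminus: 65.0
    u_wminus: 0.03
    tau_wplus: 280.0
    tau_fi: 0.11
    tau_o1: 6.0
    tau_o2: 6.0
    tau_so1: 43.0
    tau_so2: 0.2
    k_so: 2.0
    u_so: 0.65
    tau_s1: 2.7342
    tau_s2: 3.0
    k_s: 2.0994
    u_s: 0.9087
    tau_si: 2.8723
    tau_winf: 0.07
    w_infstar: 0.94
  EPI:
    u_o: 0.0
    u_u: 1.55
    theta_v: 0.3
    theta_w: 0.13
    theta_vminus: 0.006
    theta_o: 0.006
    tau_v1minus: 60.0
    tau_v2minus: 1150.0
    tau_vplus: 1.4506
    tau_w1minus: 60.0
    tau_w2minus: 15.0
    k_wminus: 65.0
    u_wminus: 0.03
    tau_wplus: 200.0
    tau_fi: 0.11
    tau_o1: 400.0
    tau_o2: 6.0
    tau_so1: 30.0181
    tau_so2: 0.9957
    k_so: 2.0458
    u_so: 0.65
    tau_s1: 2.7342
    tau_s2: 16.0
    k_s: 2.0994
    u_s: 0.9087
    tau_si: 1.8875
    tau_winf: 0.07
    w_infstar: 0.94
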