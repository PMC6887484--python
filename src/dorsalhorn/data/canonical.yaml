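# Canonical model parameters (derived by tuning against the package's
# classification and receptive-field constraint suites, then frozen).
#
# Units: capacitance pF, conductances nS, potentials mV, times ms,
# RF amplitudes nS, RF widths/positions mm.

neurons:
  inhibitory_tonic:
    label: inhibitory_tonic
    C: 20.0
    gL: 20.0
    EL: -70.0
    gNa: 200.0
    ENa: 50.0
    gK: 200.0
    EK: -100.0
    beta_m: -13.0
    gamma_m: 18.0
    beta_w: -10.0
    gamma_w: 10.0
    phi_w: 0.15
    gA: 0.0
    beta_a: -40.0
    gamma_a: 10.0
    beta_b: -65.0
    gamma_b: 6.0
    tau_b: 150.0
    g_tonic: 15.0
  excitatory_delayed:
    label: excitatory_delayed
    C: 20.0
    gL: 8.0
    EL: -70.0
    gNa: 200.0
    ENa: 50.0
    gK: 200.0
    EK: -100.0
    beta_m: -1.2
    gamma_m: 18.0
    beta_w: -10.0
    gamma_w: 10.0
    phi_w: 0.15
    gA: 60.0
    beta_a: -40.0
    gamma_a: 10.0
    beta_b: -65.0
    gamma_b: 6.0
    tau_b: 150.0
    g_tonic: 0.0
  excitatory_single:
    label: excitatory_single
    C: 20.0
    gL: 20.0
    EL: -70.0
    gNa: 200.0
    ENa: 50.0
    gK: 200.0
    EK: -100.0
    beta_m: -1.2
    gamma_m: 18.0
    beta_w: -23.0
    gamma_w: 10.0
    phi_w: 0.15
    gA: 40.0
    beta_a: -40.0
    gamma_a: 10.0
    beta_b: -65.0
    gamma_b: 6.0
    tau_b: 150.0
    g_tonic: 0.0

# Center-surround receptive fields: narrow + broad excitatory Gaussians
# plus a broad inhibitory Gaussian.  Adapting (excitatory) units carry
# strong excitation balanced by strong inhibition; non-adapting
# (inhibitory) units carry weaker versions of both.
receptive_fields:
  adapting:
    cell_class: adapting
    center: [0.0, 0.0]
    A_En: 11.7
    w_En: 1.35
    A_Eb: 4.9
    w_Eb: 6.0
    A_I: 9.9
    w_I: 6.9
    theta: 1.0
  non_adapting:
    cell_class: non_adapting
    center: [0.0, 0.0]
    A_En: 7.9
    w_En: 1.9
    A_Eb: 1.6
    w_Eb: 10.5
    A_I: 3.85
    w_I: 8.7
    theta: 1.0
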