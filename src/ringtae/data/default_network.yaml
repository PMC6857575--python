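# Default ring-network configuration: the parameter set fitted to
# tuning-curve shifts in macaque V1, with the standard adapt-then-test
# protocol (20 deg adapter for 200 ms, 0 deg test).
network:
  tau: 8.0          # membrane time constant, ms
  alpha: 3.88       # rate gain, Hz/mV
  j_lgn: 11.04      # feedforward drive strength
  kappa_lgn: 0.47   # feedforward tuning concentration
  j_cortex: 2.84    # recurrent strength, mV/Hz
  r_ie: 1.24        # inhibition/excitation ratio
  kappa_e: 1.12     # excitatory profile concentration
  kappa_i: 0.56     # inhibitory profile concentration
  n_units: 256

solver:
  rtol: 1.0e-6
  atol: 1.0e-9
  dt_out: 1.0       # output grid step, ms
  method: RK45

protocol:
  label: adapt+20_test0
  epochs:
    - {orientation: 20.0, contrast: 1.0, duration: 200.0}
    - {orientation: 0.0, contrast: 1.0, duration: 500.0}
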