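# P15 (50 uM syringe) titrated into RecO (2 uM cell), 1:1 binding truth.
kind: ITC
noise_sd: 0.1
truth:
  n: 1.0
  K_obs: 1.2e+7
  dH_obs: -5.2
design:
  n_injections: 28
  injection_volume_ul: 10.0
  syringe_uM: 50.0
  cell_uM: 2.0
  V0_ml: 1.4
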