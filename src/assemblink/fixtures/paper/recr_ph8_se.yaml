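# RecR-alone sedimentation equilibrium design at pH 8.0:
# 4/8/12 uM monomer loadings at 20/25/30 krpm, dimer-tetramer truth.
kind: SE
noise_sd: 0.005
truth:
  L_obs: 2.16e+5
  dimer_mass_kDa: 43.9
  vbar_ml_g: 0.711
design:
  loadings_uM_monomer: [4.0, 8.0, 12.0]
  speeds_rpm: [20000.0, 25000.0, 30000.0]
  pH: 8.0
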