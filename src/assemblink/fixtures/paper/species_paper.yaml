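# Species table: masses (kDa), partial specific volumes (ml/g),
# buffer sedimentation coefficients (S) and 230 nm extinction
# coefficients (M^-1 cm^-1).  vbar_ml_g holds the experimentally
# determined values; vbar_seq_ml_g the sequence-based alternatives.
species:
  RecO:
    mass_kDa: 27.4
    vbar_ml_g: 0.734
    vbar_seq_ml_g: 0.743
    s_S: 0.8
    eps_230: 1.55e+5
  RecR_dimer:
    mass_kDa: 43.9
    vbar_ml_g: 0.711
    vbar_seq_ml_g: 0.731
    s_S: 1.2
    eps_230: 1.06e+5
  RecR_tetramer:
    mass_kDa: 87.8
    vbar_ml_g: 0.711
    s_S: 1.7
    eps_230: 2.12e+5
  RecR2O:
    mass_kDa: 71.3
    vbar_ml_g: 0.720
    s_S: 1.4
    eps_230: 2.61e+5
  RecR4O:
    mass_kDa: 115.2
    vbar_ml_g: 0.716
    s_S: 1.9
    eps_230: 3.67e+5
  RecR4O2:
    mass_kDa: 142.6
    vbar_ml_g: 0.720
    s_S: 2.5
    eps_230: 5.22e+5
  P15:
    mass_kDa: 1.7
    vbar_ml_g: 0.704
    s_S: 0.0
    eps_230: 0.0
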