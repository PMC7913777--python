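# Reacting-system velocity simulation, constants without the SSB-Ct peptide:
# positively cooperative RecO binding to the RecR tetramer.
kind: SV
noise_sd: 0.005
truth:
  variant: no_p15
  L_obs: 2.16e+5
  K2: 10.0
  K3: 5.0e+5
  K4: 4.0e+8
design:
  O_total_uM: 1.5
  ratio_R_to_O: 6.0
  rotor_speed_rpm: 42000.0
  meniscus_cm: 6.14
  bottom_cm: 7.2
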