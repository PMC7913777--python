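# Tetramerization constants L_obs (M^-1) vs pH, 50 mM NaCl column.
# The pH 9.0 row is an upper limit and is excluded from fitting.
pH,L_obs,SE,upper_limit
6.4,2.67e5,0.04e5,0
7.0,1.65e6,0.03e6,0
7.5,5.68e5,0.07e5,0
8.0,2.16e5,0.05e5,0
8.5,4.32e3,0.99e3,0
9.0,500,,1
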