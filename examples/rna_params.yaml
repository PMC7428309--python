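# RNA likelihood-proxy kinetics (rates s^-1, delays s)
r_on: 0.805
r_b: 0.2
r_deg: 0.5
d_on: 0.047
d_off: 1.6
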