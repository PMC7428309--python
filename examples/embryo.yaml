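L0: 5.6
architecture: null
cycle: 11
decay_length: 20.0
delta_x: 2.0
error_rate: 0.32
seed: null
x0: 45.0
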