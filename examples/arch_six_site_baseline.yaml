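N: 6
k: 6
mu:
- 0.13285714285714287
- 0.11071428571428572
- 0.08857142857142858
- 0.06642857142857143
- 0.04428571428571429
- 0.022142857142857145
nu:
- 0.0154
- 0.0308
- 0.046200000000000005
- 0.0616
- 0.077
- 0.09240000000000001
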