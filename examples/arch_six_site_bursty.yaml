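N: 6
k: 2
mu:
- 0.07142857142857144
- 0.05952380952380953
- 0.04761904761904762
- 0.03571428571428572
- 0.02380952380952381
- 0.011904761904761906
nu:
- 0.08
- 0.16
- 0.24
- 0.32
- 0.4
- 0.48
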