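age,sex,p5,p85,p95
12,boy,15.35,23.32,26.35
12,girl,15.20,22.22,24.77
13,boy,15.82,23.93,27.02
13,girl,15.71,22.83,25.38
14,boy,16.32,24.40,27.48
14,girl,16.25,23.31,25.83
15,boy,16.83,24.74,27.77
15,girl,16.78,23.67,26.11
16,boy,17.33,24.95,27.89
16,girl,17.27,23.89,26.24
17,boy,17.80,25.08,27.89
17,girl,17.68,23.99,26.24
18,boy,18.20,25.18,27.85
18,girl,17.96,23.98,26.15
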