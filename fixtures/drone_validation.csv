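trial,measured_m,analyzed_m
1,71.5,70.41
2,71.5,70.28
3,71.5,71.08
4,71.5,73.86
5,71.5,73.61
6,71.5,72.30
7,71.5,71.76
8,71.5,72.39
9,71.5,71.98
10,71.5,72.35
11,71.5,71.75
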