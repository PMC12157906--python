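user_id,ml,random,distance,hedlm_paramA,hedlm_paramB
4,53.92,59.82,62.89,67.70,64.42
5,70.51,85.15,88.30,87.23,88.83
6,69.22,67.61,71.04,72.45,71.57
7,59.97,49.93,62.26,65.14,61.93
8,52.57,68.90,79.40,83.19,81.87
9,43.52,61.64,65.81,65.25,66.19
10,19.10,62.69,90.51,89.88,86.83
11,52.85,48.30,51.55,57.24,59.49
12,71.45,73.17,81.67,83.81,84.25
13,49.11,49.88,50.81,52.76,58.89
14,34.79,50.95,56.66,59.31,58.64
15,36.39,52.47,57.40,60.85,59.37
17,45.46,47.95,59.73,59.97,59.18
18,39.99,62.91,63.79,63.00,64.08
19,74.83,44.11,73.20,74.90,70.93
20,70.46,61.36,75.43,76.68,77.57
21,60.01,63.02,64.93,64.93,65.28
22,37.07,58.30,61.46,63.11,59.63
23,17.32,58.49,67.70,66.11,68.09
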