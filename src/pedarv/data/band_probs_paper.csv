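age_years,3-5.9 kg,6-9.9 kg,10-13.9 kg,14-19.9 kg,20-24.9 kg,25-34.9 kg,35+ kg
0.5,0.246,0.754,0.000,0.000,0.000,0.000,0.000
1,0.001,0.908,0.091,0.000,0.000,0.000,0.000
2,0.000,0.285,0.706,0.009,0.000,0.000,0.000
3,0.000,0.044,0.842,0.113,0.000,0.000,0.000
4,0.000,0.003,0.593,0.398,0.005,0.000,0.000
5,0.000,0.000,0.262,0.696,0.039,0.003,0.000
6,0.000,0.000,0.070,0.779,0.135,0.016,0.001
7,0.000,0.000,0.011,0.638,0.292,0.057,0.003
8,0.000,0.000,0.001,0.403,0.439,0.147,0.010
9,0.000,0.000,0.000,0.197,0.481,0.293,0.029
10,0.000,0.000,0.000,0.073,0.390,0.464,0.073
11,0.000,0.000,0.000,0.019,0.234,0.586,0.162
12,0.000,0.000,0.000,0.003,0.096,0.591,0.310
13,0.000,0.000,0.000,0.000,0.023,0.465,0.512
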