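# Per-candidate z-scores of the seven pregrowth constraining parameters
# (unloaded SA/LA/WT, loaded SA/LA, EDV, EDP at 22 weeks) and the cumulative
# postgrowth dimension scores (SA, LA summed over 22-40 weeks).
# All scores are absolute deviations from the reference mean in SD units.
model,unloaded_sa,unloaded_la,wall_thickness,loaded_sa,loaded_la,edv,edp,post_sa,post_la
1,0.26,0.24,4.08,1.15,1.13,1.62,1.09,5.55,5.88
2,1.77,1.35,3.55,2.46,0.16,0.75,1.09,24.35,10.72
3,0.28,1.30,1.40,1.28,0.04,1.95,1.09,20.24,18.52
4,0.28,1.26,5.05,1.33,0.08,1.94,1.09,8.90,21.87
5,3.28,0.74,1.27,3.77,0.85,1.25,1.09,44.51,12.29
6,4.83,0.64,2.91,5.02,0.99,2.25,1.09,67.86,5.60
7,2.53,0.74,2.04,3.16,0.70,0.40,1.09,32.38,6.80
8,3.24,0.19,1.43,3.71,1.38,1.66,1.09,43.98,9.39
9,1.74,0.19,1.84,2.44,1.22,0.20,1.09,22.56,8.51
10,1.78,0.74,0.10,2.52,0.63,0.46,1.09,21.76,9.81
11,1.46,0.43,2.03,2.21,0.95,0.63,1.09,18.48,5.32
12,2.67,0.37,0.81,3.25,0.63,0.55,1.09,34.72,9.71
13,2.21,0.38,0.21,2.88,1.01,0.11,1.09,27.73,9.56
14,1.93,0.74,0.06,2.65,0.64,0.32,1.09,23.87,9.31
15,2.22,0.74,1.94,2.90,0.68,0.09,1.09,28.16,8.57
16,1.74,0.24,3.76,2.41,1.33,0.02,1.09,23.92,5.24
17,1.18,0.99,0.28,0.53,0.39,0.72,0.74,14.99,9.73
18,0.59,0.79,0.30,1.83,0.67,0.71,0.74,7.11,8.19
19,0.29,0.88,0.39,1.57,0.57,0.80,0.74,12.37,4.21
20,0.29,1.02,0.33,1.58,0.44,1.05,0.74,6.95,8.69
21,0.29,0.96,0.38,1.56,0.49,1.06,0.74,8.41,6.68
22,0.06,0.88,0.36,1.55,0.57,1.03,0.74,9.40,5.11
23,0.00,0.96,0.38,1.32,0.49,0.97,0.74,5.44,6.71
24,0.00,0.84,0.42,1.30,0.62,0.95,0.74,5.29,5.25
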