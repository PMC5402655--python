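id,lawfulness,richness,syntactic,interpretability,consistency,clarity,semantic,comprehensiveness,pragmatic,history,social,q_ew,q_mod
RxNORM,0.91,0.21,0.56,0.97,0.54,1.00,0.83,0.22,0.22,0.96,0.96,0.64,0.69
DIKB,1.00,0.67,0.84,0.96,0.87,0.98,0.93,0.00,0.00,0.00,0.00,0.44,0.75
DINTO,1.00,0.49,0.75,0.80,0.88,1.00,0.88,0.03,0.03,0.00,0.00,0.41,0.69
PVOnto,1.00,0.15,0.58,0.93,0.96,0.99,0.95,0.00,0.00,0.00,0.00,0.38,0.66
VANDF,0.91,0.21,0.56,0.96,0.37,1.00,0.77,0.05,0.05,0.03,0.03,0.35,0.57
VO,1.00,0.38,0.69,0.89,0.51,1.00,0.79,0.00,0.00,0.00,0.00,0.37,0.63
DRON,0.96,0.44,0.70,0.10,0.98,1.00,0.69,0.71,0.71,0.01,0.01,0.53,0.64
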