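# Demonstration study: 6 treated animals (3 sacrificed at 1 h, 3 at 72 h),
# 3 non-treated controls, 64x64x8 tumor grids, acquisition noise SD = S0/40.
# The three candidate feature vectors of the emulated study are compared.
seed: 7
design:
  n_treated: 6
  n_treated_72h: 3
  n_control: 3
protocol:
  shape: [64, 64, 8]
lesions:
  fractions_1h: [0.1, 0.2, 0.3, 0.2, 0.267, 0.333]
  fractions_72h: [0.1, 0.2, 0.3, 0.3, 0.4, 0.5]
feature_vectors:
  - [ADC]
  - [T2, ADC]
  - [T1, T2, ADC]
alpha: 0.05
r2_threshold: 0.7
rim_thickness: 3
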