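name: eastern_europe_synthetic
stature_mm:
  female:
    mean: 1620.0
    sd: 62.0
  male:
    mean: 1770.0
    sd: 67.0
proportions_of_stature:
  shoulder_height: 0.818
  eye_height: 0.936
  upper_arm_length: 0.186
  forearm_length: 0.146
  hand_length: 0.108
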