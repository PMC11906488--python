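name: no-od-n1000
scenario:
  N: 1000
  generations: 10000
  U_neutral: 1.37
  U_deleterious: 0.07
  U_overdominant: 0.0
  od_s: 0.02
  od_h: 1.5
  region:
    length_bp: 90000000
    total_cM: 100.0
dfe:
  beta: 0.33
  mean_s: -0.2
  mean_h_target: 0.283
  sterile_threshold: -0.9
  clamp_s: -1.0
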