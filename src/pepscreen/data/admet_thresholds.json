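{
  "caco2_optimal_gt": -5.15,
  "ppb_acceptable_lt": 90.0,
  "bbb_positive_ge": 0.1,
  "vd_optimal_min": 0.04,
  "vd_optimal_max": 20.0,
  "t_half_low_lt": 3.0,
  "t_half_high_gt": 8.0
}
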