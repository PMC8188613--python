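{
  "initial_mt": 200.0,
  "initial_fa": 1.0,
  "step_length": 2.0,
  "mt_decay": 0.01,
  "mt_split_concentration": 5.0,
  "fa_branch_boost": 1.2,
  "fa_sd": 0.25,
  "k_bif": 0.1,
  "k_term": 0.5,
  "direction_jitter": 0.25,
  "branch_half_angle": 0.5,
  "max_compartments": 2000,
  "seed": 0
}
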