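{
  "design": {
    "standard_numerosities": [8, 12, 24, 50],
    "conditions": ["symmetry", "random"],
    "tasks": ["ST", "ST_WD", "DT"],
    "sessions_per_cell": 2,
    "trials_per_session": 50,
    "n_participants": 26
  },
  "geometry": {
    "field_diameter": 10.0,
    "dot_diameter": 0.3,
    "min_separation": 0.3,
    "exclusion_width": 1.6,
    "exclusion_height": 1.6
  },
  "population": {
    "bias_mean": {"ST": 0.9213, "ST_WD": 0.936, "DT": 0.97},
    "bias_sd": {"ST": 0.045, "ST_WD": 0.042, "DT": 0.025},
    "noise_mean": {"ST": 0.2096, "ST_WD": 0.2096, "DT": 0.3984},
    "noise_sd": {"ST": 0.03, "ST_WD": 0.03, "DT": 0.055},
    "conj_accuracy_mean": 0.96,
    "conj_accuracy_sd": 0.03,
    "conj_deficit_mean": 0.02,
    "conj_deficit_sd": 0.015,
    "lapse": 0.02
  },
  "master_seed": 0
}
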