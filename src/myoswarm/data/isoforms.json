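[
  {"label": "chicken skeletal", "k_on": 900.0, "k_off": 1600.0, "delta_plus": 5.0},
  {"label": "median", "k_on": 2000.0, "k_off": 2500.0, "delta_plus": 10.0},
  {"label": "baseline", "k_on": 1250.0, "k_off": 1500.0, "delta_plus": 7.5},
  {"label": "low", "k_on": 1000.0, "k_off": 1500.0, "delta_plus": 5.0},
  {"label": "high", "k_on": 3000.0, "k_off": 3500.0, "delta_plus": 15.0}
]
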