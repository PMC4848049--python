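{
  "_comment": "Double-entry bookkeeping for the worked-example fixtures: every transcribed per-site value is listed a second time here, and a test cross-checks the fixture files against this table. Forces are grams; null means the source survey printed no value for that site.",
  "set1": {
    "n_sites": 6,
    "map_positive": ["B3", "D1"],
    "in_pattern": ["A4", "B2", "B3", "C1", "C4"],
    "printed_cf": {"B3": 7.3, "D1": 8.9},
    "supra_reference": ["A4", "B2", "C1", "C4"]
  },
  "set2": {
    "n_sites": 4,
    "map_positive": ["A1", "C2"],
    "in_pattern": ["B2", "B3"],
    "printed_cf": {"B2": 8.9},
    "supra_reference": ["B3"]
  },
  "set3": {
    "n_sites": 4,
    "map_positive": ["A2", "C2"],
    "in_pattern": ["B2", "B3"],
    "printed_cf": {"A2": 11.57, "C2": 11.96, "B3": 11.0},
    "supra_reference": ["B2"]
  },
  "endocardial_mi": {
    "n_sites": 9,
    "map_positive": ["2", "3", "7", "8", "9"],
    "in_pattern": ["1", "4", "5", "6"],
    "printed_cf": {},
    "supra_reference": ["1", "4", "5", "6"]
  }
}
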