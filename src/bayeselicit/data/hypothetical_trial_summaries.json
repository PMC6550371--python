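{
  "dataset_1": {
    "n_P": 20,
    "n_A": 20,
    "xbar_P_mm": -30.0,
    "xbar_A_mm": -30.0,
    "s2_mm2": 4.6,
    "note": "broadly consistent with consensus prior opinion"
  },
  "dataset_2": {
    "n_P": 20,
    "n_A": 20,
    "xbar_P_mm": -20.0,
    "xbar_A_mm": -30.0,
    "s2_mm2": 21.3,
    "note": "variance larger than expected; pamidronate disappointing; adalimumab superior"
  },
  "dataset_3": {
    "n_P": 20,
    "n_A": 20,
    "xbar_P_mm": -20.0,
    "xbar_A_mm": -10.0,
    "s2_mm2": 4.6,
    "note": "both arms disappointing; pamidronate superior"
  }
}
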