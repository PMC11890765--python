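{
  "default": {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
    "F": 1, "Cl": 1, "Br": 1, "I": 1
  },
  "hypervalent": {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 5, "S": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 1
  },
  "charge_adjust": {
    "N": {"+1": 4, "-1": 2},
    "O": {"+1": 3, "-1": 1},
    "S": {"+1": 3, "-1": 1},
    "P": {"+1": 4, "-1": 2},
    "C": {"-1": 3, "+1": 3},
    "B": {"-1": 4}
  }
}
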