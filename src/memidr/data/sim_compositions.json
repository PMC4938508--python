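{
  "disordered": {
    "P": 0.11, "E": 0.15, "S": 0.13, "D": 0.09, "Q": 0.07,
    "R": 0.07, "K": 0.06, "G": 0.09, "N": 0.04, "T": 0.04,
    "A": 0.04, "H": 0.02, "L": 0.02, "V": 0.02, "I": 0.01,
    "M": 0.01, "F": 0.01, "Y": 0.01, "C": 0.005, "W": 0.005
  },
  "ordered": {
    "L": 0.11, "I": 0.07, "V": 0.08, "F": 0.06, "A": 0.09,
    "G": 0.07, "Y": 0.04, "W": 0.02, "C": 0.03, "M": 0.03,
    "T": 0.06, "S": 0.06, "E": 0.04, "K": 0.04, "D": 0.04,
    "N": 0.04, "Q": 0.03, "R": 0.04, "H": 0.02, "P": 0.03
  },
  "tm": {
    "L": 0.25, "I": 0.15, "V": 0.15, "F": 0.12, "A": 0.12,
    "G": 0.08, "M": 0.05, "W": 0.03, "C": 0.03, "T": 0.02
  }
}
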