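{
  "description": "Residue-appearance counts at the four engineered-mutation sites among 500 homologous spermine-synthase sequences. 'X' aggregates residues not listed individually in the published profile; '-' is the gap category. Percentages use the full 500-sequence denominator.",
  "n_sequences": 500,
  "sites": {
    "165": {"wt": "S", "target": "D", "counts": {"D": 428, "S": 57, "N": 10, "Y": 1, "-": 4, "X": 0}},
    "175": {"wt": "L", "target": "E", "counts": {"E": 380, "L": 103, "T": 4, "I": 4, "-": 2, "X": 7}},
    "178": {"wt": "T", "target": "H", "counts": {"Q": 203, "H": 167, "T": 114, "D": 10, "-": 2, "X": 4}},
    "206": {"wt": "C", "target": "R", "counts": {"R": 386, "C": 45, "Y": 38, "W": 11, "-": 1, "X": 19}}
  }
}
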