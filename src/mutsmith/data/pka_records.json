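{
  "description": "Externally computed pKa values (consumed as input, never recomputed here) for titratable residues of the C monomer: wild type, the 175/178 pair mutant, and the quadruple mutant. Residues absent from a table were not titratable in that state.",
  "tables": {
    "WT": {"ASP201": 0.0, "ASP276": 9.7},
    "Pmut": {"GLU175": 2.926, "HIS178": 3.573, "ASP201": 14.0},
    "Fmut": {"ASP276": 9.4}
  }
}
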