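{
  "description": "Published dimer-affinity changes (kcal/mol) for the engineered spermine-synthase variants, per force field and averaged. Positive = mutation increases dimer affinity.",
  "force_fields": ["amber98", "charmm27", "oplsaa"],
  "records": {
    "SDmut": {"amber98": -1.71, "charmm27": -1.61, "oplsaa": -0.22, "ave": -1.18},
    "CRmut": {"amber98": 3.79, "charmm27": 0.78, "oplsaa": 1.41, "ave": 1.99},
    "Pmut": {"amber98": 0.50, "charmm27": -1.47, "oplsaa": -1.20, "ave": -0.73},
    "sum": {"amber98": 2.58, "charmm27": -2.3, "oplsaa": -0.01, "ave": 0.08},
    "Fmut": {"amber98": 0.36, "charmm27": -2.11, "oplsaa": -0.07, "ave": -0.61}
  }
}
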