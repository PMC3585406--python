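{
  "description": "Published folding-stability changes (kcal/mol) for the engineered spermine-synthase variants: per-force-field values for monomers C and D, force-field averages, C/D averages, and the two-parameter (affine) adjusted predictions. 'sum' is the additivity row (single mutants summed, the 175/178 pair taken together). Positive = mutant monomer more stable.",
  "force_fields": ["amber98", "charmm27", "oplsaa"],
  "records": {
    "SDmut": {
      "mutations": ["S165D"],
      "C": {"amber98": 51.07, "charmm27": 109.92, "oplsaa": 90.89},
      "D": {"amber98": 42.60, "charmm27": 107.56, "oplsaa": 97.66},
      "ave_force_fields": {"C": 83.96, "D": 82.60},
      "ave_cd": 83.28,
      "adjusted": 6.66
    },
    "CRmut": {
      "mutations": ["C206R"],
      "C": {"amber98": 194.73, "charmm27": 276.20, "oplsaa": 56.20},
      "D": {"amber98": 203.56, "charmm27": 276.14, "oplsaa": 81.06},
      "ave_force_fields": {"C": 175.71, "D": 186.92},
      "ave_cd": 181.32,
      "adjusted": 15.77
    },
    "Pmut": {
      "mutations": ["L175E", "T178H"],
      "C": {"amber98": 3.48, "charmm27": 106.25, "oplsaa": 139.76},
      "D": {"amber98": 9.07, "charmm27": 114.50, "oplsaa": 167.26},
      "ave_force_fields": {"C": 83.16, "D": 96.94},
      "ave_cd": 90.05,
      "adjusted": 7.29
    },
    "sum": {
      "mutations": ["S165D", "C206R", "L175E", "T178H"],
      "C": {"amber98": 249.28, "charmm27": 492.37, "oplsaa": 286.85},
      "D": {"amber98": 255.23, "charmm27": 498.20, "oplsaa": 345.98},
      "ave_force_fields": {"C": 342.83, "D": 366.46},
      "ave_cd": 354.65,
      "adjusted": 31.89
    },
    "Fmut": {
      "mutations": ["S165D", "L175E", "T178H", "C206R"],
      "C": {"amber98": 249.59, "charmm27": 508.35, "oplsaa": 292.48},
      "D": {"amber98": 274.07, "charmm27": 493.99, "oplsaa": 314.02},
      "ave_force_fields": {"C": 350.14, "D": 360.69},
      "ave_cd": 355.42,
      "adjusted": 31.97
    }
  }
}
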