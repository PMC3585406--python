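{
  "description": "Published anisotropic-network-model mode frequencies (GHz) of wild-type and quadruple-mutant spermine synthase, computed on structures minimized under three force fields; modes 1-3 and the force-field averages.",
  "force_fields": ["amber98", "charmm27", "oplsaa"],
  "records": {
    "WT": {
      "amber98": [29.21, 34.77, 39.55],
      "charmm27": [24.93, 27.26, 32.77],
      "oplsaa": [28.98, 34.05, 37.96],
      "ave": [27.71, 32.02, 36.76]
    },
    "Fmut": {
      "amber98": [30.00, 35.56, 40.76],
      "charmm27": [24.38, 27.34, 32.71],
      "oplsaa": [29.26, 33.66, 37.59],
      "ave": [27.88, 32.19, 37.02]
    }
  }
}
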