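[
  {
    "name": "Oxidation",
    "aliases": ["U:Oxidation", "Unimod:35"],
    "formula": "O1",
    "targets": ["M", "W"],
    "neutral_losses": [{"formula": "C1H4O1S1", "targets": ["M"]}]
  },
  {
    "name": "Phospho",
    "aliases": ["U:Phospho", "Unimod:21", "Phosphorylation"],
    "formula": "H1O3P1",
    "targets": ["S", "T", "Y"],
    "neutral_losses": ["H3O4P1"]
  },
  {
    "name": "Carbamidomethyl",
    "aliases": ["U:Carbamidomethyl", "Unimod:4", "CAM"],
    "formula": "C2H3N1O1",
    "targets": ["C"]
  },
  {
    "name": "Acetyl",
    "aliases": ["U:Acetyl", "Unimod:1"],
    "formula": "C2H2O1",
    "targets": ["K", "N-term"]
  },
  {
    "name": "Deamidated",
    "aliases": ["U:Deamidated", "Unimod:7", "Deamidation"],
    "formula": "H-1N-1O1",
    "targets": ["N", "Q"]
  },
  {
    "name": "Gln->pyro-Glu",
    "aliases": ["U:Gln->pyro-Glu", "Unimod:28", "Pyro-glu"],
    "formula": "H-3N-1",
    "targets": ["N-term:Q"]
  },
  {
    "name": "DSS",
    "aliases": ["XL:DSS"],
    "formula": "C8H10O2",
    "targets": ["K", "N-term"],
    "linker": true
  },
  {
    "name": "Disulfide",
    "aliases": ["XL:Disulfide", "SS"],
    "formula": "H-2",
    "targets": ["C"],
    "linker": true,
    "breakage": [
      {"retained": "H-1", "partner": "(empty)"},
      {"retained": "H-1", "partner": "H1"},
      {"retained": "H-2S-1", "partner": "S1"}
    ]
  }
]
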