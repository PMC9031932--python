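{
  "version": "iupac-2021-abridged",
  "atomic_weights": {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "Na": 22.990,
    "Al": 26.982,
    "P": 30.974,
    "F": 18.998,
    "I": 126.90
  },
  "monoisotopic_masses": {
    "C": 12.0,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
    "Cl": 34.968853,
    "Br": 78.918338,
    "Na": 22.989769,
    "Al": 26.981538,
    "P": 30.973762,
    "F": 18.998403,
    "I": 126.904473
  },
  "chlorine": {
    "mass_35": 34.968853,
    "mass_37": 36.965903,
    "natural_abundance_35": 0.7576,
    "natural_abundance_37": 0.2424
  }
}
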