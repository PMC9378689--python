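{
  "name": "bondi-1964-extended",
  "comment": "van der Waals radii (Angstrom), Bondi (1964) values for the common biomolecular elements, extended with customary values for metals; curated data used by the accessible-surface-area calculation",
  "default": 1.7,
  "radii": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "P": 1.8,
    "S": 1.8,
    "SE": 1.9,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "ZN": 1.39,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "MN": 1.95,
    "FE": 1.94,
    "CU": 1.4,
    "NI": 1.63,
    "CO": 1.92,
    "CD": 1.58
  }
}
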