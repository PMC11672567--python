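{
  "name": "bondi",
  "description": "Bondi (1964) van der Waals radii in Angstrom, by element symbol.",
  "reference": "Bondi, A. (1964) J. Phys. Chem. 68, 441-451",
  "default": 1.70,
  "radii": {
    "H": 1.20,
    "HE": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NE": 1.54,
    "SI": 2.10,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "AR": 1.88,
    "AS": 1.85,
    "SE": 1.90,
    "BR": 1.85,
    "KR": 2.02,
    "TE": 2.06,
    "I": 1.98,
    "XE": 2.16,
    "ZN": 1.39,
    "CU": 1.40,
    "NI": 1.63,
    "FE": 1.70,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31
  }
}
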