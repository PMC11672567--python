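{
  "description": "Aliases for chemically modified residues: 3-letter PDB residue name to the one-letter code of the parent amino acid.",
  "aliases": {
    "MSE": "M",
    "SEC": "C",
    "PYL": "K",
    "HYP": "P",
    "SEP": "S",
    "TPO": "T",
    "PTR": "Y",
    "CSO": "C",
    "CME": "C",
    "MLY": "K",
    "KCX": "K",
    "FME": "M"
  }
}
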