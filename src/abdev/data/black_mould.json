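{
  "name": "black_mould",
  "description": "Normalized Black & Mould (1991) hydrophobicity indices, scaled to [0, 1] with Phe maximal and Arg minimal.",
  "reference": "Black, S.D. & Mould, D.R. (1991) Anal. Biochem. 193, 72-82",
  "normalization": "linear rescaling of the relative hydrophobicities to the unit interval",
  "index": {
    "A": 0.616,
    "C": 0.680,
    "D": 0.028,
    "E": 0.043,
    "F": 1.000,
    "G": 0.501,
    "H": 0.165,
    "I": 0.943,
    "K": 0.283,
    "L": 0.943,
    "M": 0.738,
    "N": 0.236,
    "P": 0.711,
    "Q": 0.251,
    "R": 0.000,
    "S": 0.359,
    "T": 0.450,
    "V": 0.825,
    "W": 0.878,
    "Y": 0.880
  }
}
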