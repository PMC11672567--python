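{
  "name": "kabat",
  "description": "Kabat CDR/framework boundaries by chain type, inclusive ranges over the numeric part of the Kabat position (insertion codes fall in the range of their parent number). Positions beyond FR4 belong to the constant domain.",
  "heavy": {
    "FR1": [1, 30],
    "CDR1": [31, 35],
    "FR2": [36, 49],
    "CDR2": [50, 65],
    "FR3": [66, 94],
    "CDR3": [95, 102],
    "FR4": [103, 113]
  },
  "light": {
    "FR1": [1, 23],
    "CDR1": [24, 34],
    "FR2": [35, 49],
    "CDR2": [50, 56],
    "FR3": [57, 88],
    "CDR3": [89, 97],
    "FR4": [98, 107]
  }
}
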