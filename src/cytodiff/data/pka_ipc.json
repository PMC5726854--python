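{
  "name": "IPC_protein",
  "comment": "pKa set of the Isoelectric Point Calculator, protein-optimised values",
  "acidic": {
    "Cterm": 2.869,
    "D": 3.872,
    "E": 4.412,
    "C": 7.555,
    "Y": 10.85
  },
  "basic": {
    "Nterm": 9.094,
    "H": 5.637,
    "K": 9.052,
    "R": 11.84
  }
}
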