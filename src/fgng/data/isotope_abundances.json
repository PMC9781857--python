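{
  "comment": "Natural isotopic abundances, IUPAC 2021 representative values. m0 = lightest isotope, m1 = +1 mass shift isotope (2H, 13C, 15N, 17O, 33S, 29Si). Heavier shifts (+2 and beyond) are not tracked.",
  "elements": {
    "H": {"m0": 0.999885, "m1": 0.000115},
    "C": {"m0": 0.9893, "m1": 0.0107},
    "N": {"m0": 0.99636, "m1": 0.00364},
    "O": {"m0": 0.99757, "m1": 0.00038},
    "S": {"m0": 0.9499, "m1": 0.0075},
    "Si": {"m0": 0.92223, "m1": 0.04685}
  }
}
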