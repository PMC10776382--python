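{
  "_comment": "Reduced per-element Lennard-Jones parameters: rmin_half in Angstrom (pair minimum at the sum), epsilon the well depth in package units.",
  "C": {"rmin_half": 1.90, "epsilon": 0.08},
  "N": {"rmin_half": 1.80, "epsilon": 0.17},
  "O": {"rmin_half": 1.70, "epsilon": 0.16},
  "P": {"rmin_half": 2.10, "epsilon": 0.40},
  "S": {"rmin_half": 2.00, "epsilon": 0.45},
  "H": {"rmin_half": 0.90, "epsilon": 0.02}
}
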