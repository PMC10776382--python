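{
  "B": {
    "reference_residue": "DA",
    "torsions_deg": {
      "alpha": -38.87389960353567,
      "beta": 119.01710405157985,
      "gamma": 91.20739339247447,
      "delta": 67.45046876422562,
      "epsilon": -132.9439683506507,
      "zeta": -96.96996191718662,
      "nu0": -0.23614336962495744,
      "nu1": 66.69486776208636,
      "nu2": -50.345330775152455,
      "chi": -79.58034968165776
    },
    "dyad_phi_deg": -127.47674991983072,
    "dyad_z": -1.3312736741692446,
    "twist_deg": 36.000556274449586,
    "rise": 3.3953916086940055
  },
  "A": {
    "reference_residue": "A",
    "torsions_deg": {
      "alpha": 0.6395434737856901,
      "beta": -102.88967861374667,
      "gamma": 14.31301661133484,
      "delta": -7.626012746188321,
      "epsilon": -134.69754377263175,
      "zeta": 74.29867751339158,
      "nu0": -9.061288587633838,
      "nu1": -39.673710866908564,
      "nu2": 77.43704606373264,
      "chi": 24.38058539835512
    },
    "dyad_phi_deg": -161.12957451364971,
    "dyad_z": 7.481726859110339,
    "twist_deg": 32.69994625642916,
    "rise": 2.8099340178969414
  }
}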