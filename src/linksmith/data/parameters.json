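{
  "comment": "Target bond lengths (A) and sigmas for the shipped atom-energy types; peptide values follow Engh & Huber-style stereochemistry. Keys are 'type1|type2|order' (typed) or 'El1|El2|order' (element fallback); pairs are symmetric.",
  "covalent_radii": {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07, "S": 1.05,
    "SE": 1.20, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39
  },
  "typed_bonds": {
    "C2|N2h1|single": [1.329, 0.014],
    "C2|O2|double": [1.231, 0.020],
    "C2|O3h1|single": [1.308, 0.020],
    "C2|C3h1|single": [1.525, 0.021],
    "C2|C3h2|single": [1.516, 0.018],
    "C3h1|N3h2|single": [1.489, 0.020],
    "C3h2|N3h2|single": [1.489, 0.020],
    "C3h2|N3h3|single": [1.489, 0.020],
    "C3h1|C3h2|single": [1.530, 0.020],
    "C3h2|C3h2|single": [1.520, 0.030],
    "C3h2|S3h1|single": [1.808, 0.033],
    "C3h2|S3|single": [1.808, 0.033],
    "S3|S3|single": [2.031, 0.020]
  },
  "typed_angles": {
    "C3h1|C2|O2": [120.8, 1.7],
    "C3h2|C2|O2": [120.8, 1.7],
    "O2|C2|O3h1": [123.0, 1.6],
    "C3h1|C2|O3h1": [116.2, 2.0],
    "C3h2|C2|O3h1": [116.2, 2.0],
    "C2|N2h1|C3h1": [121.7, 1.8],
    "C2|N2h1|C3h2": [121.7, 1.8],
    "C3h2|S3h1|S3h1": [103.8, 1.8],
    "C3h2|S3|S3": [103.8, 1.8]
  },
  "element_bonds": {
    "C|C|single": [1.530, 0.020],
    "C|C|double": [1.340, 0.020],
    "C|C|triple": [1.200, 0.020],
    "C|C|aromatic": [1.390, 0.020],
    "C|C|deloc": [1.390, 0.020],
    "C|N|single": [1.470, 0.020],
    "C|N|double": [1.280, 0.020],
    "C|N|triple": [1.150, 0.020],
    "C|N|aromatic": [1.340, 0.020],
    "C|N|deloc": [1.340, 0.020],
    "C|O|single": [1.430, 0.020],
    "C|O|double": [1.230, 0.020],
    "C|O|deloc": [1.250, 0.020],
    "C|S|single": [1.810, 0.020],
    "C|S|double": [1.670, 0.020],
    "C|SE|single": [1.950, 0.030],
    "C|P|single": [1.800, 0.030],
    "C|F|single": [1.350, 0.020],
    "C|CL|single": [1.740, 0.020],
    "C|BR|single": [1.900, 0.030],
    "C|I|single": [2.100, 0.030],
    "N|N|single": [1.450, 0.020],
    "N|N|double": [1.250, 0.020],
    "N|O|single": [1.400, 0.020],
    "N|O|double": [1.210, 0.020],
    "O|P|single": [1.600, 0.020],
    "O|P|double": [1.480, 0.020],
    "O|S|single": [1.580, 0.020],
    "O|S|double": [1.440, 0.020],
    "S|S|single": [2.030, 0.020],
    "C|H|single": [1.089, 0.020],
    "N|H|single": [1.016, 0.020],
    "O|H|single": [0.966, 0.020],
    "S|H|single": [1.340, 0.020],
    "SE|H|single": [1.460, 0.030],
    "P|H|single": [1.410, 0.030]
  },
  "defaults": {
    "bond_sigma": 0.020,
    "fallback_bond_sigma": 0.030,
    "angle_sigma": 3.0,
    "tetrahedral_angle": 109.47,
    "trigonal_angle": 120.0,
    "linear_angle": 180.0,
    "torsion_sp3_sigma": 15.0,
    "torsion_sp2_sigma": 5.0,
    "plane_sigma": 0.02,
    "chiral_sigma": 0.2
  }
}
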