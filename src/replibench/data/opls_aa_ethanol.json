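{
 "format": "replibench-forcefield-1",
 "name": "OPLS-AA-ethanol",
 "units": {
  "sigma": "angstrom",
  "epsilon": "kJ/mol",
  "charge": "e",
  "mass": "g/mol",
  "bond_r0": "angstrom",
  "bond_k": "kJ/mol/angstrom^2 (u = k/2 (r-r0)^2)",
  "angle_theta0": "degree",
  "angle_k": "kJ/mol/rad^2 (u = k/2 (theta-theta0)^2)",
  "dihedral_c": "kJ/mol (u = c0 + c1(1+cos) + c2(1-cos2) + c3(1+cos3))",
  "r_cut": "angstrom"
 },
 "provenance": "10.1021/ja9621760; energies kcal/mol (thermochemical calorie), 1-4 LJ and Coulomb scaled by 0.5",
 "mixing_rule": "geometric",
 "r_cut": 10.0,
 "lrc_mode": "tail",
 "atom_types": {
  "CT3": {
   "sigma": 3.5,
   "epsilon": 0.276144,
   "source_label": "OPLS-AA",
   "stated_digits": null,
   "charge": -0.18,
   "mass": 12.011
  },
  "CT2": {
   "sigma": 3.5,
   "epsilon": 0.276144,
   "source_label": "OPLS-AA",
   "stated_digits": null,
   "charge": 0.145,
   "mass": 12.011
  },
  "HC": {
   "sigma": 2.5,
   "epsilon": 0.12552,
   "source_label": "OPLS-AA",
   "stated_digits": null,
   "charge": 0.06,
   "mass": 1.008
  },
  "OH": {
   "sigma": 3.12,
   "epsilon": 0.7112800000000001,
   "source_label": "OPLS-AA",
   "stated_digits": null,
   "charge": -0.683,
   "mass": 15.999
  },
  "HO": {
   "sigma": 1.0,
   "epsilon": 0.0,
   "source_label": "no-LJ",
   "stated_digits": null,
   "charge": 0.418,
   "mass": 1.008
  }
 },
 "bond_terms": {
  "CC": {
   "r0": 1.529,
   "k": 2242.6240000000003
  },
  "CH": {
   "r0": 1.09,
   "k": 2845.12
  },
  "CO": {
   "r0": 1.41,
   "k": 2677.76
  },
  "OHb": {
   "r0": 0.945,
   "k": 4627.504
  }
 },
 "angle_terms": {
  "CCH": {
   "theta0": 110.7,
   "k": 313.8
  },
  "HCH": {
   "theta0": 107.8,
   "k": 276.144
  },
  "CCO": {
   "theta0": 108.0,
   "k": 418.40000000000003
  },
  "HCO": {
   "theta0": 109.5,
   "k": 292.88
  },
  "COH": {
   "theta0": 108.5,
   "k": 460.24
  }
 },
 "dihedral_terms": {
  "HCCH": {
   "c0": 0.0,
   "c1": 0.0,
   "c2": 0.0,
   "c3": 0.6652560000000001
  },
  "HCCO": {
   "c0": 0.0,
   "c1": 0.0,
   "c2": 0.0,
   "c3": 0.9790560000000001
  },
  "HCOH": {
   "c0": 0.0,
   "c1": 0.0,
   "c2": 0.0,
   "c3": 0.736384
  },
  "CCOH": {
   "c0": 0.0,
   "c1": -0.744752,
   "c2": -0.364008,
   "c3": 1.029264
  }
 },
 "exclusion_policy": {
  "2": [
   0.0,
   0.0
  ],
  "3": [
   0.0,
   0.0
  ],
  "4": [
   0.5,
   0.5
  ]
 },
 "pair_overrides": {}
}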