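{
 "format": "replibench-forcefield-1",
 "name": "TraPPE-UA",
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
 "provenance": "10.1021/jp972543+ (alkanes); 10.1021/jp001044x (aromatics); eps/k_B in K, sigma in Angstrom, fixed C-C bonds",
 "mixing_rule": "lorentz",
 "r_cut": 14.0,
 "lrc_mode": "tail",
 "atom_types": {
  "CH4": {
   "sigma": 3.73,
   "epsilon": 1.2305404674866796,
   "source_label": "TraPPE-UA",
   "stated_digits": null,
   "charge": 0.0,
   "mass": 16.043
  },
  "CH3": {
   "sigma": 3.75,
   "epsilon": 0.8148173365790176,
   "source_label": "TraPPE-UA",
   "stated_digits": null,
   "charge": 0.0,
   "mass": 15.035
  },
  "CH2": {
   "sigma": 3.95,
   "epsilon": 0.38246528043504907,
   "source_label": "TraPPE-UA",
   "stated_digits": null,
   "charge": 0.0,
   "mass": 14.027
  },
  "CHar": {
   "sigma": 3.695,
   "epsilon": 0.41988036221673863,
   "source_label": "TraPPE-UA",
   "stated_digits": null,
   "charge": 0.0,
   "mass": 13.019
  }
 },
 "bond_terms": {
  "CC": {
   "r0": 1.54,
   "k": null
  },
  "CCar": {
   "r0": 1.4,
   "k": null
  }
 },
 "angle_terms": {
  "CCC": {
   "theta0": 114.0,
   "k": 519.6539136345775
  }
 },
 "dihedral_terms": {
  "CCCC": {
   "c0": 0.0,
   "c1": 2.9518836633229446,
   "c2": -0.5669632059318694,
   "c3": 6.579400558997023
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
   0.0,
   0.0
  ]
 },
 "pair_overrides": {}
}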