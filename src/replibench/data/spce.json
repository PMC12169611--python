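{
 "format": "replibench-forcefield-1",
 "name": "SPC/E",
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
 "provenance": "10.1021/j100308a038; LJ converted from A=0.37122 (kJ/mol)^(1/6) nm, B=0.3428 (kJ/mol)^(1/12) nm at full double precision",
 "mixing_rule": "lorentz",
 "r_cut": 9.0,
 "lrc_mode": "tail",
 "atom_types": {
  "OW": {
   "sigma": 3.1655578901998815,
   "epsilon": 0.6501695808187481,
   "source_label": "original-HP",
   "stated_digits": null,
   "charge": -0.8476,
   "mass": 15.999
  },
  "HW": {
   "sigma": 1.0,
   "epsilon": 0.0,
   "source_label": "no-LJ",
   "stated_digits": null,
   "charge": 0.4238,
   "mass": 1.008
  }
 },
 "bond_terms": {
  "OH": {
   "r0": 1.0,
   "k": null
  }
 },
 "angle_terms": {
  "HOH": {
   "theta0": 109.47,
   "k": null
  }
 },
 "dihedral_terms": {},
 "exclusion_policy": {
  "2": [
   0.0,
   0.0
  ],
  "3": [
   0.0,
   0.0
  ]
 },
 "pair_overrides": {}
}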