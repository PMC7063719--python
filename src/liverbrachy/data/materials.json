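{
 "water": {
  "density": 1.0,
  "composition": {
   "H": 0.1119,
   "O": 0.8881
  }
 },
 "air": {
  "density": 0.0012,
  "composition": {
   "C": 0.000124,
   "N": 0.755268,
   "O": 0.231781,
   "Ar": 0.012827
  }
 },
 "lung": {
  "density": 0.26,
  "composition": {
   "H": 0.103,
   "C": 0.105,
   "N": 0.031,
   "O": 0.749,
   "Na": 0.002,
   "P": 0.002,
   "S": 0.003,
   "Cl": 0.003,
   "K": 0.002
  }
 },
 "adipose": {
  "density": 0.95,
  "composition": {
   "H": 0.114,
   "C": 0.598,
   "N": 0.007,
   "O": 0.278,
   "Na": 0.001,
   "S": 0.001,
   "Cl": 0.001
  }
 },
 "soft_tissue_male": {
  "density": 1.03,
  "composition": {
   "H": 0.105,
   "C": 0.256,
   "N": 0.027,
   "O": 0.602,
   "Na": 0.001,
   "P": 0.002,
   "S": 0.003,
   "Cl": 0.002,
   "K": 0.002
  }
 },
 "soft_tissue_female": {
  "density": 1.02,
  "composition": {
   "H": 0.106,
   "C": 0.315,
   "N": 0.024,
   "O": 0.547,
   "Na": 0.001,
   "P": 0.002,
   "S": 0.002,
   "Cl": 0.001,
   "K": 0.002
  }
 },
 "liver": {
  "density": 1.06,
  "composition": {
   "H": 0.102,
   "C": 0.139,
   "N": 0.03,
   "O": 0.716,
   "Na": 0.002,
   "P": 0.003,
   "S": 0.003,
   "Cl": 0.002,
   "K": 0.003
  }
 },
 "cortical_bone": {
  "density": 1.92,
  "composition": {
   "H": 0.034,
   "C": 0.155,
   "N": 0.042,
   "O": 0.435,
   "Na": 0.001,
   "Mg": 0.002,
   "P": 0.103,
   "S": 0.003,
   "Ca": 0.225
  }
 }
}
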