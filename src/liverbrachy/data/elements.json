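{
 "H": {
  "Z": 1,
  "A": 1.008
 },
 "C": {
  "Z": 6,
  "A": 12.011
 },
 "N": {
  "Z": 7,
  "A": 14.007
 },
 "O": {
  "Z": 8,
  "A": 15.999
 },
 "Na": {
  "Z": 11,
  "A": 22.99
 },
 "Mg": {
  "Z": 12,
  "A": 24.305
 },
 "P": {
  "Z": 15,
  "A": 30.974
 },
 "S": {
  "Z": 16,
  "A": 32.06
 },
 "Cl": {
  "Z": 17,
  "A": 35.45
 },
 "Ar": {
  "Z": 18,
  "A": 39.948
 },
 "K": {
  "Z": 19,
  "A": 39.098
 },
 "Ca": {
  "Z": 20,
  "A": 40.078
 },
 "Fe": {
  "Z": 26,
  "A": 55.845
 }
}
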