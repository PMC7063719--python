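{
 "liver": {
  "V5Gy_pct": 67.0,
  "V10Gy_pct": 33.0
 },
 "oar_d1cc_Gy": {
  "bile_duct": 21.0,
  "bowel": 15.0,
  "colon": 20.0,
  "duodenum": 12.0,
  "esophagus": 12.0,
  "gall_bladder": 20.0,
  "heart": 22.0,
  "stomach": 12.0,
  "kidney": null
 }
}
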