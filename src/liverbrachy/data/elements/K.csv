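energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,121.855,121.671
0.015,33.87,33.691
0.02,13.552,13.3776
0.03,3.75258,3.58683
0.04,1.56173,1.40369
0.05,0.831438,0.680375
0.06,0.524734,0.380008
0.08,0.292167,0.158514
0.1,0.211435,0.0871325
0.15,0.147664,0.0414129
0.2,0.125881,0.0326601
0.3,0.105261,0.0297157
0.4,0.0933841,0.0294026
0.5,0.0849643,0.0292276
0.6,0.0784696,0.0289566
0.8,0.0688335,0.0281723
1,0.0618449,0.0272338
1.25,0.0552748,0.0260199
1.5,0.0502211,0.0248482
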