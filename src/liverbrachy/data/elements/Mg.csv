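energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,23.8278,23.641
0.015,6.73148,6.54963
0.02,2.78148,2.60436
0.03,0.87273,0.704322
0.04,0.442581,0.282015
0.05,0.296558,0.14308
0.06,0.233151,0.0861123
0.08,0.181155,0.0453659
0.1,0.15957,0.0332804
0.15,0.135363,0.0274136
0.2,0.122204,0.0274931
0.3,0.105445,0.0286924
0.4,0.0942953,0.0292912
0.5,0.0860433,0.0294158
0.6,0.0795708,0.0292664
0.8,0.0698743,0.0285631
1,0.0628049,0.0276406
1.25,0.0561446,0.0264221
1.5,0.0510163,0.0252378
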