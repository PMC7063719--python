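energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,67.4979,67.309
0.015,18.8238,18.64
0.02,7.58254,7.40351
0.03,2.15875,1.98852
0.04,0.944178,0.781875
0.05,0.537799,0.382662
0.06,0.36593,0.217301
0.08,0.233347,0.0960894
0.1,0.185285,0.0576295
0.15,0.143193,0.0340764
0.2,0.125996,0.0302608
0.3,0.107236,0.0296532
0.4,0.0955674,0.0298604
0.5,0.0870949,0.029855
0.6,0.0804976,0.0296493
0.8,0.0706556,0.0288978
1,0.0634964,0.0279519
1.25,0.0567577,0.0267137
1.5,0.0515712,0.025514
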