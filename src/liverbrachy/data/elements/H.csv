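energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,0.388828,0.0133684
0.015,0.377477,0.0120769
0.02,0.369887,0.0139902
0.03,0.357146,0.018758
0.04,0.345829,0.0231957
0.05,0.335498,0.0271085
0.06,0.325991,0.0305391
0.08,0.309051,0.036205
0.1,0.294388,0.0406295
0.15,0.265026,0.0481191
0.2,0.242847,0.0525408
0.3,0.211163,0.0569412
0.4,0.189195,0.0585799
0.5,0.172758,0.0589738
0.6,0.159812,0.0587334
0.8,0.140373,0.0573649
1,0.126183,0.0555259
1.25,0.112807,0.0530845
1.5,0.102506,0.0507078
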