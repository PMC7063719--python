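energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,360.721,360.544
0.015,99.9991,99.8276
0.02,39.7964,39.6294
0.03,10.7695,10.6107
0.04,4.28829,4.13688
0.05,2.13431,1.98959
0.06,1.23477,1.09611
0.08,0.56222,0.434174
0.1,0.337386,0.218297
0.15,0.177249,0.0754548
0.2,0.134484,0.0451734
0.3,0.104502,0.0321254
0.4,0.0908857,0.029588
0.5,0.0820811,0.0286823
0.6,0.0755518,0.0281156
0.8,0.0660912,0.0271355
1,0.0593203,0.026161
1.25,0.0529897,0.0249619
1.5,0.0481329,0.0238242
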