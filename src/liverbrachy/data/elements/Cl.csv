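energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,80.6321,80.4506
0.015,22.455,22.2784
0.02,9.01954,8.8475
0.03,2.53817,2.37459
0.04,1.08777,0.931813
0.05,0.603257,0.454186
0.06,0.398948,0.256131
0.08,0.242474,0.110584
0.1,0.186755,0.0640922
0.15,0.139907,0.0350571
0.2,0.121966,0.029975
0.3,0.103279,0.02873
0.4,0.091922,0.0287844
0.5,0.0837331,0.0287315
0.6,0.077374,0.028514
0.8,0.0679021,0.0277771
1,0.0610179,0.0268633
1.25,0.0545403,0.0256713
1.5,0.0495557,0.0245175
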