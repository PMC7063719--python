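energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,3.62966,3.44052
0.015,1.14086,0.956794
0.02,0.5637,0.384418
0.03,0.280885,0.110423
0.04,0.213507,0.050981
0.05,0.187834,0.0324836
0.06,0.17452,0.0256869
0.08,0.159657,0.0222115
0.1,0.150195,0.0223645
0.15,0.13401,0.0247435
0.2,0.122529,0.0266627
0.3,0.106425,0.0287355
0.4,0.0953268,0.0295295
0.5,0.0870361,0.0297175
0.6,0.0805103,0.0295921
0.8,0.0707147,0.0288995
1,0.0635654,0.027972
1.25,0.0568269,0.0267417
1.5,0.0516373,0.0255442
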