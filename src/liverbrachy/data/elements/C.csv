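energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,2.165,1.97594
0.015,0.735288,0.551294
0.02,0.402667,0.223459
0.03,0.237743,0.0673516
0.04,0.196674,0.0342155
0.05,0.179733,0.0244475
0.06,0.170057,0.0212861
0.08,0.157898,0.0205092
0.1,0.149324,0.0215467
0.15,0.13374,0.0245186
0.2,0.122395,0.0265684
0.3,0.106358,0.0287016
0.4,0.0952786,0.0295087
0.5,0.0869958,0.0297011
0.6,0.0804746,0.0295775
0.8,0.0706844,0.0288866
1,0.0635385,0.02796
1.25,0.0568031,0.0267304
1.5,0.0516157,0.0255335
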