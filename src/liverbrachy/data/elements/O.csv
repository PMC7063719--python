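energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,5.75424,5.565
0.015,1.72917,1.545
0.02,0.797283,0.6179
0.03,0.343458,0.1729
0.04,0.237917,0.0753
0.05,0.199578,0.04414
0.06,0.180987,0.03207
0.08,0.162203,0.02468
0.1,0.151452,0.02355
0.15,0.134397,0.0250687
0.2,0.122719,0.0267985
0.3,0.106516,0.0287835
0.4,0.0953927,0.0295585
0.5,0.087091,0.0297402
0.6,0.0805589,0.029612
0.8,0.0707558,0.028917
1,0.0636017,0.0279884
1.25,0.0568592,0.026757
1.5,0.0516665,0.0255588
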