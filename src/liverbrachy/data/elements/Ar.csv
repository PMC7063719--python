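energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,93.0319,92.8614
0.015,25.8803,25.7143
0.02,10.3727,10.2111
0.03,2.8927,2.73901
0.04,1.21971,1.07317
0.05,0.661514,0.521447
0.06,0.42667,0.292479
0.08,0.247812,0.123888
0.1,0.185019,0.0697644
0.15,0.133989,0.0354724
0.2,0.115583,0.0291474
0.3,0.0972999,0.0272537
0.4,0.0864707,0.0271464
0.5,0.0787241,0.0270444
0.6,0.0727273,0.0268183
0.8,0.0638113,0.0261098
1,0.0573375,0.0252458
1.25,0.0512487,0.0241232
1.5,0.046564,0.023038
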