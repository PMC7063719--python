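energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,16.9312,16.7502
0.015,4.81788,4.64164
0.02,2.01851,1.84687
0.03,0.664613,0.50141
0.04,0.358407,0.202802
0.05,0.253617,0.104882
0.06,0.207463,0.0649677
0.08,0.168429,0.0368359
0.1,0.151235,0.0288479
0.15,0.130277,0.0256631
0.2,0.118077,0.026293
0.3,0.102094,0.0277135
0.4,0.0913457,0.0283503
0.5,0.0833673,0.0284896
0.6,0.0771025,0.0283526
0.8,0.0677114,0.0276769
1,0.0608624,0.0267847
1.25,0.0544089,0.0256048
1.5,0.0494394,0.0244575
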