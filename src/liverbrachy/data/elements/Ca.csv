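energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,150.47,150.281
0.015,41.7962,41.6124
0.02,16.7011,16.5221
0.03,4.59859,4.42838
0.04,1.89369,1.7314
0.05,0.99273,0.837604
0.06,0.614871,0.466253
0.08,0.329343,0.192096
0.1,0.231123,0.103477
0.15,0.155351,0.0462424
0.2,0.130708,0.0349802
0.3,0.108471,0.0308945
0.4,0.0960427,0.0303407
0.5,0.0873199,0.0300843
0.6,0.0806187,0.0297742
0.8,0.0706996,0.0289449
1,0.0635153,0.0279734
1.25,0.0567648,0.0267231
1.5,0.0515736,0.0255183
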