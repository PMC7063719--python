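energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
0.01,51.9575,51.7742
0.015,14.5172,14.3388
0.02,5.86979,5.69606
0.03,1.69661,1.53143
0.04,0.761245,0.603752
0.05,0.447621,0.29708
0.06,0.31446,0.170234
0.08,0.210765,0.0775745
0.1,0.172312,0.0484396
0.15,0.136965,0.0310811
0.2,0.121492,0.0285936
0.3,0.103856,0.0285717
0.4,0.092657,0.0288969
0.5,0.0844765,0.0289326
0.6,0.0780918,0.0287501
0.8,0.0685541,0.0280335
1,0.0616111,0.0271198
1.25,0.0550741,0.0259204
1.5,0.0500421,0.024757
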