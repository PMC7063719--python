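r_cm,g
0.25,0.997403
0.5,0.998418
0.75,0.999284
1,1.000000
1.5,1.000973
2,1.001322
2.5,1.001033
3,1.000090
4,0.996185
5,0.989489
6,0.979882
8,0.951465
10,0.909985
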