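r_cm\theta_deg,0,10,20,30,45,60,75,90,105,120,135,150,160,170,180
0.5,0.92390,0.92620,0.93280,0.94293,0.96195,0.98098,0.99490,1.00000,0.99490,0.98098,0.96195,0.94293,0.93280,0.92620,0.92390
1,0.92761,0.92980,0.93608,0.94571,0.96381,0.98190,0.99515,1.00000,0.99515,0.98190,0.96381,0.94571,0.93608,0.92980,0.92761
2,0.93450,0.93648,0.94216,0.95088,0.96725,0.98363,0.99561,1.00000,0.99561,0.98363,0.96725,0.95088,0.94216,0.93648,0.93450
3,0.94073,0.94252,0.94767,0.95555,0.97037,0.98518,0.99603,1.00000,0.99603,0.98518,0.97037,0.95555,0.94767,0.94252,0.94073
5,0.95148,0.95294,0.95715,0.96361,0.97574,0.98787,0.99675,1.00000,0.99675,0.98787,0.97574,0.96361,0.95715,0.95294,0.95148
10,0.97057,0.97146,0.97401,0.97793,0.98528,0.99264,0.99803,1.00000,0.99803,0.99264,0.98528,0.97793,0.97401,0.97146,0.97057
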