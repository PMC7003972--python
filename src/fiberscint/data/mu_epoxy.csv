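energy_mev,photoelectric,compton,pair,total
0.01,0.0736389,0.20827,0,0.281909
0.015,0.0630349,0.204528,0,0.267563
0.02,0.0494853,0.200959,0,0.250444
0.03,0.0170253,0.194295,0,0.21132
0.04,0.00777626,0.188196,0,0.195972
0.05,0.0042416,0.182592,0,0.186834
0.06,0.00259209,0.177426,0,0.180018
0.08,0.00117822,0.168212,0,0.16939
0.1,0.00294555,0.160233,0,0.163179
0.15,0.00103094,0.144253,0,0.145284
0.2,0.000459507,0.132181,0,0.132641
0.3,0.000176733,0.114936,0,0.115113
0.4,9.13122e-05,0.102979,0,0.10307
0.5,5.36091e-05,0.0940319,0,0.0940855
0.6,3.77031e-05,0.0869855,0,0.0870232
0.8,1.76733e-05,0.0764048,0,0.0764225
1,1.04862e-05,0.0686811,0,0.0686916
1.25,7.36389e-06,0.0614008,0.000163579,0.0615717
1.5,5.06635e-06,0.0557936,0.000305348,0.0561041
2,2.82773e-06,0.0475934,0.000708844,0.0483051
2.5,2.23862e-06,0.0417941,0.00100329,0.0427996
3,1.88516e-06,0.0374257,0.00127592,0.0387035
4,1.47278e-06,0.0312091,0.00181028,0.0330208
5,1.23713e-06,0.0269464,0.00229011,0.0292377
6,1.11931e-06,0.023813,0.00276994,0.0265841
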