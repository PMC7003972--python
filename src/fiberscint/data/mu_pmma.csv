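energy_mev,photoelectric,compton,pair,total
0.01,0.0839929,0.208007,0,0.292
0.015,0.0718979,0.204269,0,0.276167
0.02,0.0564432,0.200705,0,0.257148
0.03,0.0194192,0.194049,0,0.213468
0.04,0.00886965,0.187958,0,0.196828
0.05,0.00483799,0.182362,0,0.1872
0.06,0.00295655,0.177202,0,0.180159
0.08,0.00134389,0.168,0,0.169344
0.1,0.00335972,0.160031,0,0.163391
0.15,0.0011759,0.144071,0,0.145247
0.2,0.000524116,0.132014,0,0.132538
0.3,0.000201583,0.114791,0,0.114992
0.4,0.000104151,0.102849,0,0.102953
0.5,6.11468e-05,0.0939131,0,0.0939743
0.6,4.30044e-05,0.0868756,0,0.0869186
0.8,2.01583e-05,0.0763083,0,0.0763285
1,1.19606e-05,0.0685944,0,0.0686064
1.25,8.39929e-06,0.0613233,0.000168752,0.0615004
1.5,5.77871e-06,0.0557232,0.000315004,0.056044
2,3.22533e-06,0.0475333,0.000731259,0.0482678
2.5,2.55338e-06,0.0417413,0.00103501,0.0427789
3,2.15022e-06,0.0373784,0.00131627,0.0386968
4,1.67986e-06,0.0311697,0.00186752,0.0330389
5,1.41108e-06,0.0269123,0.00236253,0.0292763
6,1.27669e-06,0.0237829,0.00285754,0.0266418
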