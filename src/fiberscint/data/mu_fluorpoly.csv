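energy_mev,photoelectric,compton,pair,total
0.01,0.140613,0.19275,0,0.333363
0.015,0.120365,0.189286,0,0.309651
0.02,0.0944921,0.185983,0,0.280475
0.03,0.0325098,0.179816,0,0.212326
0.04,0.0148488,0.174171,0,0.18902
0.05,0.00809932,0.168986,0,0.177085
0.06,0.00494959,0.164204,0,0.169154
0.08,0.00224981,0.155677,0,0.157927
0.1,0.00562453,0.148293,0,0.153917
0.15,0.00196859,0.133503,0,0.135472
0.2,0.000877427,0.122331,0,0.123208
0.3,0.000337472,0.106371,0,0.106708
0.4,0.00017436,0.0953048,0,0.0954791
0.5,0.000102366,0.0870247,0,0.087127
0.6,7.1994e-05,0.0805034,0,0.0805754
0.8,3.37472e-05,0.0707112,0,0.0707449
1,2.00233e-05,0.0635631,0,0.0635831
1.25,1.40613e-05,0.0568252,0.000191129,0.0570304
1.5,9.67419e-06,0.0516359,0.000356775,0.0520024
2,5.39955e-06,0.0440468,0.000828227,0.0448804
2.5,4.27464e-06,0.0386796,0.00117226,0.0398561
3,3.5997e-06,0.0346367,0.00149081,0.0361311
4,2.81226e-06,0.0288834,0.00211516,0.0310014
5,2.3623e-06,0.0249383,0.00267581,0.0276165
6,2.13732e-06,0.0220385,0.00323645,0.0252771
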