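energy_mev,photoelectric,compton,pair,total
0.01,125,0.152642,0,125.153
0.015,107,0.149899,0,107.15
0.02,84,0.147284,0,84.1473
0.03,28.9,0.1424,0,29.0424
0.04,13.2,0.13793,0,13.3379
0.05,7.2,0.133823,0,7.33382
0.06,4.4,0.130037,0,4.53004
0.08,2,0.123284,0,2.12328
0.1,5,0.117436,0,5.11744
0.15,1.75,0.105724,0,1.85572
0.2,0.78,0.0968762,0,0.876876
0.3,0.3,0.0842371,0,0.384237
0.4,0.155,0.0754736,0,0.230474
0.5,0.091,0.0689164,0,0.159916
0.6,0.064,0.0637521,0,0.127752
0.8,0.03,0.0559975,0,0.0859975
1,0.0178,0.0503368,0,0.0681368
1.25,0.0125,0.045001,0.0015,0.059001
1.5,0.0086,0.0408914,0.0028,0.0522914
2,0.0048,0.0348815,0.0065,0.0461815
2.5,0.0038,0.0306311,0.0092,0.0436311
3,0.0032,0.0274295,0.0117,0.0423295
4,0.0025,0.0228733,0.0166,0.0419733
5,0.0021,0.0197491,0.021,0.0428491
6,0.0019,0.0174527,0.0254,0.0447527
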