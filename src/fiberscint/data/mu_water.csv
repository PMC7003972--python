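energy_mev,photoelectric,compton,pair,total
0.01,0.130312,0.214098,0,0.344411
0.015,0.111547,0.210251,0,0.321799
0.02,0.0875698,0.206583,0,0.294152
0.03,0.0301282,0.199732,0,0.22986
0.04,0.013761,0.193462,0,0.207223
0.05,0.00750599,0.187702,0,0.195208
0.06,0.00458699,0.182391,0,0.186978
0.08,0.002085,0.17292,0,0.175005
0.1,0.00521249,0.164717,0,0.16993
0.15,0.00182437,0.14829,0,0.150114
0.2,0.000813149,0.13588,0,0.136693
0.3,0.000312749,0.118152,0,0.118465
0.4,0.000161587,0.105861,0,0.106022
0.5,9.48673e-05,0.0966634,0,0.0967582
0.6,6.67199e-05,0.0894198,0,0.0894865
0.8,3.12749e-05,0.078543,0,0.0785743
1,1.85565e-05,0.0706032,0,0.0706217
1.25,1.30312e-05,0.0631191,0.00019265,0.0633248
1.5,8.96548e-06,0.057355,0.000359614,0.0577236
2,5.00399e-06,0.0489253,0.000834819,0.0497651
2.5,3.96149e-06,0.0429637,0.00118159,0.0441492
3,3.33599e-06,0.038473,0.00150267,0.039979
4,2.60625e-06,0.0320825,0.002132,0.0342171
5,2.18925e-06,0.0277005,0.00269711,0.0303998
6,1.98075e-06,0.0244794,0.00326222,0.0277436
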