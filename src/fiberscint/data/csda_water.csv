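energy_mev,csda_g_cm2
0.01,0.000252
0.015,0.000515
0.02,0.000857
0.03,0.00176
0.04,0.00292
0.05,0.00432
0.06,0.00594
0.08,0.00977
0.1,0.01431
0.15,0.0282
0.2,0.0449
0.3,0.0842
0.4,0.1289
0.5,0.1766
0.6,0.2244
0.8,0.3297
1,0.4367
1.25,0.5701
1.5,0.7075
2,0.9785
2.5,1.2478
3,1.514
4,2.037
5,2.55
6,3.052
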