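energy_mev,photoelectric,compton,pair,total
0.01,0.0570714,0.207377,0,0.264448
0.015,0.0488531,0.203651,0,0.252504
0.02,0.038352,0.200097,0,0.238449
0.03,0.0131949,0.193462,0,0.206657
0.04,0.00602674,0.187389,0,0.193415
0.05,0.00328731,0.181809,0,0.185097
0.06,0.00200891,0.176665,0,0.178674
0.08,0.000913142,0.167491,0,0.168404
0.1,0.00228286,0.159546,0,0.161829
0.15,0.000799,0.143634,0,0.144433
0.2,0.000356126,0.131614,0,0.13197
0.3,0.000136971,0.114443,0,0.11458
0.4,7.07685e-05,0.102537,0,0.102608
0.5,4.1548e-05,0.0936287,0,0.0936703
0.6,2.92206e-05,0.0866125,0,0.0866417
0.8,1.36971e-05,0.0760773,0,0.076091
1,8.12697e-06,0.0683867,0,0.0683948
1.25,5.70714e-06,0.0611375,0.000154337,0.0612976
1.5,3.92651e-06,0.0555544,0.000288095,0.0558465
2,2.19154e-06,0.0473894,0.000668792,0.0480603
2.5,1.73497e-06,0.0416149,0.000946598,0.0425632
3,1.46103e-06,0.0372652,0.00120383,0.0384705
4,1.14143e-06,0.0310753,0.00170799,0.0327844
5,9.58799e-07,0.0268308,0.00216071,0.0289925
6,8.67485e-07,0.0237109,0.00261343,0.0263252
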