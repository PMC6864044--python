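# Synthetic whole-blood optical coefficient table (1/mm), 515-635 nm.
# Analytic approximation to published whole-blood spectra; constructed by
# scripts/make_coefficient_table.py and bundled as package data.  Peaks:
# HbO2 542/576 nm, Hb 555 nm; magnitudes from molar extinction at 150 g/L
# total haemoglobin; mu_s ~ smooth power law around 560 nm.  Not a copy of
# any published table; do not use for quantitative work on real data.
# columns: wavelength_nm, mu_a_hb, mu_s_hb, mu_a_hbo2, mu_s_hbo2
515.0000,14.7832,93.9888,7.4802,101.7290
516.0000,15.1440,93.7702,7.6373,101.4925
517.0000,15.5258,93.5526,7.8529,101.2569
518.0000,15.9282,93.3359,8.1339,101.0224
519.0000,16.3508,93.1202,8.4866,100.7889
520.0000,16.7929,92.9053,8.9171,100.5563
521.0000,17.2537,92.6914,9.4307,100.3248
522.0000,17.7323,92.4783,10.0315,100.0942
523.0000,18.2276,92.2662,10.7223,99.8646
524.0000,18.7385,92.0549,11.5040,99.6359
525.0000,19.2636,91.8446,12.3750,99.4082
526.0000,19.8015,91.6351,13.3317,99.1815
527.0000,20.3504,91.4264,14.3672,98.9557
528.0000,20.9086,91.2187,15.4721,98.7308
529.0000,21.4743,91.0118,16.6336,98.5069
530.0000,22.0453,90.8058,17.8362,98.2839
531.0000,22.6196,90.6006,19.0615,98.0618
532.0000,23.1950,90.3963,20.2888,97.8407
533.0000,23.7690,90.1928,21.4953,97.6205
534.0000,24.3392,89.9902,22.6569,97.4011
535.0000,24.9033,89.7884,23.7488,97.1827
536.0000,25.4585,89.5874,24.7465,96.9652
537.0000,26.0024,89.3872,25.6264,96.7485
538.0000,26.5323,89.1879,26.3670,96.5328
539.0000,27.0457,88.9894,26.9493,96.3179
540.0000,27.5399,88.7916,27.3578,96.1039
541.0000,28.0125,88.5947,27.5814,95.8908
542.0000,28.4608,88.3986,27.6136,95.6785
543.0000,28.8824,88.2033,27.4528,95.4671
544.0000,29.2751,88.0088,27.1030,95.2565
545.0000,29.6366,87.8150,26.5733,95.0468
546.0000,29.9647,87.6220,25.8779,94.8380
547.0000,30.2575,87.4299,25.0357,94.6300
548.0000,30.5132,87.2384,24.0701,94.4228
549.0000,30.7302,87.0478,23.0082,94.2164
550.0000,30.9070,86.8579,21.8800,94.0109
551.0000,31.0424,86.6688,20.7179,93.8062
552.0000,31.1353,86.4804,19.5558,93.6023
553.0000,31.1850,86.2928,18.4282,93.3992
554.0000,31.1907,86.1059,17.3696,93.1970
555.0000,31.1522,85.9197,16.4134,92.9955
556.0000,31.0694,85.7343,15.5910,92.7948
557.0000,30.9423,85.5497,14.9313,92.5949
558.0000,30.7713,85.3657,14.4591,92.3958
559.0000,30.5570,85.1825,14.1948,92.1975
560.0000,30.3001,85.0000,14.1529,92.0000
561.0000,30.0017,84.8182,14.3415,91.8032
562.0000,29.6630,84.6371,14.7613,91.6073
563.0000,29.2854,84.4568,15.4049,91.4120
564.0000,28.8706,84.2771,16.2565,91.2176
565.0000,28.4203,84.0981,17.2916,91.0239
566.0000,27.9365,83.9199,18.4772,90.8309
567.0000,27.4213,83.7423,19.7729,90.6387
568.0000,26.8768,83.5654,21.1315,90.4473
569.0000,26.3055,83.3892,22.5011,90.2566
570.0000,25.7097,83.2137,23.8269,90.0666
571.0000,25.0919,83.0388,25.0535,89.8773
572.0000,24.4546,82.8647,26.1276,89.6888
573.0000,23.8004,82.6911,27.0009,89.5010
574.0000,23.1320,82.5183,27.6318,89.3139
575.0000,22.4518,82.3461,27.9882,89.1276
576.0000,21.7624,82.1746,28.0490,88.9419
577.0000,21.0665,82.0037,27.8048,88.7570
578.0000,20.3663,81.8335,27.2588,88.5727
579.0000,19.6644,81.6639,26.4258,88.3892
580.0000,18.9631,81.4950,25.3316,88.2064
581.0000,18.2645,81.3267,24.0108,88.0242
582.0000,17.5708,81.1591,22.5052,87.8427
583.0000,16.8840,80.9920,20.8609,87.6620
584.0000,16.2060,80.8256,19.1259,87.4819
585.0000,15.5386,80.6599,17.3478,87.3024
586.0000,14.8832,80.4947,15.5712,87.1237
587.0000,14.2415,80.3302,13.8364,86.9456
588.0000,13.6147,80.1663,12.1775,86.7682
589.0000,13.0040,80.0030,10.6217,86.5915
590.0000,12.4104,79.8403,9.1891,86.4154
591.0000,11.8349,79.6782,7.8927,86.2399
592.0000,11.2782,79.5167,6.7388,86.0652
593.0000,10.7408,79.3558,5.7280,85.8910
594.0000,10.2234,79.1956,4.8559,85.7175
595.0000,9.7262,79.0359,4.1145,85.5447
596.0000,9.2494,78.8768,3.4930,85.3725
597.0000,8.7933,78.7182,2.9790,85.2009
598.0000,8.3577,78.5603,2.5593,85.0300
599.0000,7.9425,78.4029,2.2206,84.8597
600.0000,7.5477,78.2462,1.9502,84.6900
601.0000,7.1728,78.0900,1.7364,84.5209
602.0000,6.8177,77.9343,1.5686,84.3524
603.0000,6.4817,77.7793,1.4378,84.1846
604.0000,6.1645,77.6248,1.3359,84.0174
605.0000,5.8654,77.4708,1.2567,83.8508
606.0000,5.5840,77.3174,1.1947,83.6847
607.0000,5.3196,77.1646,1.1457,83.5193
608.0000,5.0715,77.0123,1.1064,83.3545
609.0000,4.8391,76.8606,1.0742,83.1903
610.0000,4.6217,76.7094,1.0473,83.0267
611.0000,4.4185,76.5588,1.0242,82.8636
612.0000,4.2289,76.4087,1.0038,82.7012
613.0000,4.0521,76.2592,0.9853,82.5393
614.0000,3.8875,76.1101,0.9683,82.3780
615.0000,3.7344,75.9617,0.9524,82.2173
616.0000,3.5920,75.8137,0.9373,82.0572
617.0000,3.4598,75.6663,0.9228,81.8976
618.0000,3.3369,75.5194,0.9088,81.7386
619.0000,3.2230,75.3730,0.8952,81.5802
620.0000,3.1172,75.2271,0.8820,81.4223
621.0000,3.0191,75.0818,0.8691,81.2650
622.0000,2.9280,74.9370,0.8566,81.1082
623.0000,2.8436,74.7926,0.8443,80.9520
624.0000,2.7651,74.6488,0.8324,80.7964
625.0000,2.6923,74.5055,0.8207,80.6413
626.0000,2.6246,74.3627,0.8092,80.4867
627.0000,2.5616,74.2204,0.7980,80.3327
628.0000,2.5029,74.0786,0.7871,80.1792
629.0000,2.4482,73.9373,0.7764,80.0263
630.0000,2.3971,73.7965,0.7659,79.8739
631.0000,2.3493,73.6562,0.7557,79.7220
632.0000,2.3045,73.5164,0.7456,79.5707
633.0000,2.2625,73.3770,0.7358,79.4198
634.0000,2.2229,73.2382,0.7263,79.2695
635.0000,2.1856,73.0998,0.7169,79.1198
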