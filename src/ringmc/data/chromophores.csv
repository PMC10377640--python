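wavelength_nm,oxy_hb,deoxy_hb,water,fat,melanin,baseline,collagen
600,17.1355,78.5931,0.0022,0.006,365.159,0.3452,0.3
620,3.9626,34.8601,0.0028,0.0055,325.781,0.3188,0.2925
640,2.3668,23.2668,0.0031,0.005,291.704,0.2993,0.285
660,1.7114,17.2777,0.0036,0.0048,262.081,0.2849,0.2775
680,1.4672,13.5263,0.0042,0.0046,236.221,0.2742,0.27
700,1.5529,9.6066,0.006,0.006,213.554,0.2663,0.2625
720,1.7885,8.5035,0.0104,0.009,193.612,0.2605,0.255
740,2.3883,7.1969,0.0256,0.012,176.004,0.2562,0.2475
760,3.1379,8.292,0.026,0.014,160.405,0.253,0.24
780,3.8019,6.565,0.0236,0.012,146.541,0.2507,0.2325
800,4.3696,4.0804,0.0206,0.011,134.182,0.2489,0.225
820,4.905,3.7109,0.0246,0.012,123.134,0.2476,0.2175
840,5.4727,3.7163,0.0356,0.015,113.229,0.2467,0.21
860,5.8475,3.8876,0.046,0.02,104.326,0.246,0.2025
880,6.1795,3.9679,0.056,0.03,96.305,0.2455,0.195
900,6.4151,4.0804,0.0679,0.05,89.06,0.2451,0.1875
920,6.6079,3.8555,0.13,0.1,82.503,0.2448,0.18
940,6.5008,3.7133,0.267,0.075,76.553,0.2446,0.1725
960,6.3562,3.5717,0.42,0.05,71.145,0.2444,0.165
980,6.0724,3.4807,0.43,0.04,66.219,0.2443,0.1575
1000,5.6654,3.4378,0.363,0.035,61.723,0.2442,0.15
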