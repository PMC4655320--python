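ga_weeks,sex,mean_g,sd_g
24,male,659,82
24,female,635,79
25,male,772,97
25,female,744,93
26,male,898,112
26,female,865,108
27,male,1038,130
27,female,1000,125
28,male,1191,149
28,female,1147,143
29,male,1356,170
29,female,1307,163
30,male,1534,192
30,female,1478,185
31,male,1723,215
31,female,1660,207
32,male,1921,240
32,female,1851,231
33,male,2127,266
33,female,2049,256
34,male,2339,292
34,female,2253,282
35,male,2553,319
35,female,2460,307
36,male,2767,346
36,female,2666,333
37,male,2979,372
37,female,2870,359
38,male,3184,398
38,female,3067,383
39,male,3378,422
39,female,3255,407
40,male,3560,445
40,female,3430,429
41,male,3725,466
41,female,3589,449
42,male,3870,484
42,female,3728,466
43,male,3992,499
43,female,3846,481
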