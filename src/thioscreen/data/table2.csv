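sample_number,catalog_id,aza_dose,asa_dose,tgn,risk_ratio_printed
1,5842535,75,3600,195,2.60
2,5779006,50,2250,474,9.48
3,770916,25,1500,423,16.92
4,4872959,25,3000,130,5.20
5,5459355,50,3000,287,5.74
6,6232762,50,2250,243,4.86
7,2639084,50,2250,164,3.28
8,0156158,50,1500,144,2.88
9,5571916,50,3000,50,1.00
10,3281892,25,2250,464,18.56
11,2852065,100,3000,353,3.53
12,162980,50,2250,572,11.44
13,0777935,100,0,253,2.53
14,5445356,100,2250,178,1.78
15,6007418,50,3600,152,3.04
16,5294675,25,2250,144,5.76
17,4549910,100,3000,87,0.87
18,5999831,25,2400,163,6.52
19,2002116,25,2400,54,2.16
20,6158273,50,4000,365,7.30
21,6176417,50,3600,293,5.86
22,4255178,50,3600,557,11.14
23,6230023,50,3600,99,1.98
24,0185310,75,2000,595,7.93
25,0437466,50,3000,488,9.76
26,1830237,50,2250,359,7.18
27,1996388,50,3000,146,2.92
28,2240525,50,1500,301,6.02
29,2366881,50,3000,287,5.74
30,4782476,50,2000,193,3.86
31,4916624,50,3000,201,4.02
32,5478242,100,2250,380,3.80
33,5480939,25,3000,292,11.68
34,5615377,100,4000,113,1.13
35,5796199,100,0,50,0.50
36,5892802,75,3000,366,4.88
37,5906785,50,2000,561,11.22
38,6176174,50,0,288,5.76
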