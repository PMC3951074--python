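age,qx
0,0.0004049179985705642
1,0.00040552711882912984
2,0.0004062104742256212
3,0.00040697711193737884
4,0.0004078371817226589
5,0.0004088020702883721
6,0.0004098845520319472
7,0.0004110989581513902
8,0.00041246136636319264
9,0.0004139898137369702
10,0.0004157045354645783
11,0.00041762823272262217
12,0.00041978637317185985
13,0.0004222075280704285
14,0.0004249237504594383
15,0.00042797099942293304
16,0.0004313896160359487
17,0.0004352248572911943
18,0.00043952749506714905
19,0.0004443544880555761
20,0.0004497697355279051
21,0.00045584492290606793
22,0.00046266047030496527
23,0.00047030659658053864
24,0.00047888451293220946
25,0.0004885077618173028
26,0.0004993037188476546
27,0.0005114152774801095
28,0.0005250027387146972
29,0.0005402459307051188
30,0.0005573465862005467
31,0.0005765310091142561
32,0.0005980530652950344
33,0.0006221975368123633
34,0.0006492838838022541
35,0.0006796704632271444
36,0.0007137592598318587
37,0.000752001191212659
38,0.0007949020563335907
39,0.0008430292051050392
40,0.0008970190158968938
41,0.0009575852781834593
42,0.0010255285890344856
43,0.0011017468850055279
44,0.001187247245278411
45,0.0012831591178035229
46,0.001390749137873848
47,0.0015114377281780778
48,0.0016468176911255128
49,0.0017986750282925623
50,0.0019690122484212758
51,0.002160074454682137
52,0.002374378534113819
53,0.0026147458074418095
54,0.002884338536031872
55,0.0031867007246760837
56,0.0035258037043349733
57,0.0039060970278573803
58,0.004332565263997834
59,0.004810791330495778
60,0.005347027065159549
61,0.005948271794128823
62,0.0066223597177668125
63,0.007378056995523408
64,0.0082251694696307
65,0.009174662020938085
66,0.010238790594986447
67,0.011431247967827574
68,0.01276732433297123
69,0.014264083775266445
70,0.015940557644381292
71,0.01781795573701328
72,0.019919896026913575
73,0.022272653425124078
74,0.024905427684567383
75,0.02785063005266808
76,0.031144187585694483
77,0.03482586312396019
78,0.03893958773417161
79,0.043533800890707686
80,0.0486617917179919
81,0.054382032167700656
82,0.06075848996446587
83,0.0678609054222169
84,0.07576501170837824
85,0.08455267271827271
86,0.09431190633854214
87,0.10513675348357243
88,0.11712694490286246
89,0.13038730849983227
90,0.14502685004343152
91,0.16115743017837192
92,0.17889195133163227
93,0.19834196065455434
94,0.21961457122651595
95,0.24280860570474339
96,0.26800987749939387
97,0.29528554824565345
98,0.3246775414608014
99,0.3561950559999243
100,0.38980631453308145
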