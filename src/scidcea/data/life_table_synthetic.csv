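age,qx
0,0.0033
1,0.0002219685384404757
2,0.00022415986437562818
3,0.00022656956979993925
4,0.0002292194170029349
5,0.00023213333683635984
6,0.00023533764477978725
7,0.0002388612785280131
8,0.00024273605924440833
9,0.00024699697883390215
10,0.0002516825158267455
11,0.00025683498272044414
12,0.00026250090790980174
13,0.0002687314556462095
14,0.00027558288780948903
15,0.00028311707165096234
16,0.0002914020380789806
17,0.0003005125955111154
18,0.0003105310048162613
19,0.00032154772141723686
20,0.0003336622112246612
21,0.00034698384773357294
22,0.00036163289834068024
23,0.00037774160873438323
24,0.0003954553950852313
25,0.00041493415472459994
26,0.00043635370705041865
27,0.0004599073775585216
28,0.00048580773916151454
29,0.000514288526352602
30,0.0005456067392922703
31,0.0005800449565728227
32,0.0006179138772420822
33,0.0006595551146804102
34,0.000705344267117658
35,0.0007556942919879628
36,0.0008110592139456418
37,0.0008719381992509101
38,0.0009388800323715252
39,0.0010124880340870446
40,0.0010934254641266072
41,0.001182421455459437
42,0.0012802775318094817
43,0.0013878747648085055
44,0.0015061816324709598
45,0.0016362626463891639
46,0.0017792878212448127
47,0.0019365430669412431
48,0.0021094415909053144
49,0.002299536405918956
50,0.0025085340472377204
51,0.0027383096117642447
52,0.0029909232416711617
53,0.0032686381851271262
54,0.00357394057765803
55,0.003909561099155412
56,0.004278498673589981
57,0.0046840463910324814
58,0.00512981984454175
59,0.005619788087712019
60,0.00615830743201784
61,0.006750158316300325
62,0.007400585493522405
63,0.008115341791872677
64,0.008900735717928931
65,0.009763683178282467
66,0.010711763601974345
67,0.011753280748360906
68,0.012897328482388226
69,0.014153861790278666
70,0.015533773291516173
71,0.017048975475621453
72,0.018712488851927
73,0.020538536144283026
74,0.022542642586636297
75,0.024741742275311895
76,0.027154290404395764
77,0.02980038104577587
78,0.03270186992804902
79,0.03588250141044891
80,0.03936803852982729
81,0.0431863946098785
82,0.04736776445036561
83,0.05194475254695752
84,0.05695249511525102
85,0.06242877189067564
86,0.0684141027340035
87,0.07495182297532788
88,0.08208813016440708
89,0.08987209345209812
90,0.09835561520144143
91,0.1075933326212073
92,0.11764244524481071
93,0.12856245197581517
94,0.1404147792432795
95,0.15326227964218264
96,0.1671685784021637
97,0.18219724330832043
98,0.19841075252936557
99,0.21586923450405648
100,0.23462895499561243
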