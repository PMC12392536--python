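age,qx
18,3.430289901784622e-05
19,3.867632606591176e-05
20,4.360732835217984e-05
21,4.916698874157799e-05
22,5.543545125241689e-05
23,6.250307586752601e-05
24,7.047174045571314e-05
25,7.945630852579377e-05
26,8.958628391442236e-05
27,0.00010100767618659301
28,0.00011388510354415349
29,0.00012840416343640193
30,0.0001447741048926643
31,0.0001632308409020844
32,0.00018404034401664493
33,0.00020750247380596498
34,0.00023395529093306333
35,0.0002637799195229773
36,0.000297406027256919
37,0.0003353180013527801
38,0.000378061908392735
39,0.00042625333696910683
40,0.0004805862344738898
41,0.0005418428632205652
42,0.0006109050166218655
43,0.000688766653553885
44,0.0007765481285126885
45,0.0008755122169469276
46,0.000987082159468522
47,0.001112861975763102
48,0.00125465932922586
49,0.001414511256915718
50,0.001594713116668478
51,0.0017978511444268763
52,0.002026839060340402
53,0.0022849592122452522
54,0.002575908799993809
55,0.002903851783970568
56,0.0032734771460990464
57,0.0036900642417083684
58,0.004159556055573277
59,0.004688641254840253
60,0.005284846014613098
61,0.005956636677472593
62,0.0067135343943396375
63,0.007566242978253257
64,0.008526791281252333
65,0.009608691472723141
66,0.01082711464878483
67,0.01219908522787927
68,0.01374369557645505
69,0.015482342245865532
70,0.017438985068637725
71,0.019640430135285825
72,0.022116637321807797
73,0.024901052525324596
74,0.02803096404438632
75,0.03154788155399568
76,0.035497934803744524
77,0.03993228742694743
78,0.04490755899019283
79,0.05048624552094472
80,0.056737125094340146
81,0.06373563049379372
82,0.07156416532898324
83,0.0803123331449247
84,0.09007704084830437
85,0.10096242811299372
86,0.11307956328284252
87,0.12654583377211637
88,0.14148394537960107
89,0.1580204308883777
90,0.17628355485331793
91,0.19640049020027295
92,0.21849363556051493
93,0.2426759434922099
94,0.2690451433958341
95,0.29767677477318166
96,0.32861600349583897
97,0.36186828383182335
98,0.3973890601518475
99,0.43507288119218257
100,0.47474252946193884
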