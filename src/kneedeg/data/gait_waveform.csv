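stance_percent,bw_multiple
0,0.00
4,0.60
8,1.40
12,2.20
15,2.50
20,2.35
25,2.05
30,1.75
35,1.55
40,1.45
45,1.40
50,1.40
55,1.45
60,1.60
65,1.85
70,2.15
75,2.45
80,2.70
85,2.80
88,2.70
92,2.20
96,1.20
100,0.25
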