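id,k,start,stop,status,treatment,number,size
2,1,0,1,0,0,1,3
3,1,0,4,0,0,2,1
4,1,0,7,0,0,1,1
5,1,0,10,0,0,5,1
6,1,0,6,1,0,4,1
6,2,6,10,0,0,4,1
7,1,0,14,0,0,1,1
8,1,0,18,0,0,1,1
9,1,0,5,1,0,1,3
9,2,5,18,0,0,1,3
10,1,0,12,1,0,1,1
10,2,12,16,1,0,1,1
10,3,16,18,0,0,1,1
11,1,0,23,0,0,3,3
12,1,0,10,1,0,1,3
12,2,10,15,1,0,1,3
12,3,15,23,0,0,1,3
13,1,0,3,1,0,1,1
13,2,3,16,1,0,1,1
13,3,16,23,1,0,1,1
14,1,0,3,1,0,3,1
14,2,3,9,1,0,3,1
14,3,9,21,1,0,3,1
14,4,21,23,0,0,3,1
15,1,0,7,1,0,2,3
15,2,7,10,1,0,2,3
15,3,10,16,1,0,2,3
15,4,16,24,1,0,2,3
16,1,0,3,1,0,1,1
16,2,3,15,1,0,1,1
16,3,15,25,1,0,1,1
17,1,0,26,0,0,1,2
18,1,0,1,1,0,8,1
18,2,1,26,0,0,8,1
19,1,0,2,1,0,1,4
19,2,2,26,1,0,1,4
20,1,0,25,1,0,1,2
20,2,25,28,0,0,1,2
21,1,0,29,0,0,1,4
22,1,0,29,0,0,1,2
23,1,0,29,0,0,4,1
24,1,0,28,1,0,1,6
24,2,28,30,1,0,1,6
25,1,0,2,1,0,1,5
25,2,2,17,1,0,1,5
25,3,17,22,1,0,1,5
25,4,22,30,0,0,1,5
26,1,0,3,1,0,2,1
26,2,3,6,1,0,2,1
26,3,6,8,1,0,2,1
26,4,8,12,1,0,2,1
26,5,12,26,1,0,2,1
26,6,26,30,0,0,2,1
27,1,0,12,1,0,1,3
27,2,12,15,1,0,1,3
27,3,15,24,1,0,1,3
27,4,24,31,0,0,1,3
28,1,0,32,0,0,1,2
29,1,0,34,0,0,2,1
30,1,0,36,0,0,2,1
31,1,0,29,1,0,3,1
31,2,29,36,0,0,3,1
32,1,0,37,0,0,1,2
33,1,0,9,1,0,4,1
33,2,9,17,1,0,4,1
33,3,17,22,1,0,4,1
33,4,22,24,1,0,4,1
33,5,24,40,0,0,4,1
34,1,0,16,1,0,5,1
34,2,16,19,1,0,5,1
34,3,19,23,1,0,5,1
34,4,23,29,1,0,5,1
34,5,29,34,1,0,5,1
34,6,34,40,1,0,5,1
35,1,0,41,0,0,1,2
36,1,0,3,1,0,1,1
36,2,3,43,0,0,1,1
37,1,0,6,1,0,2,6
37,2,6,43,0,0,2,6
38,1,0,3,1,0,2,1
38,2,3,6,1,0,2,1
38,3,6,9,1,0,2,1
38,4,9,44,0,0,2,1
39,1,0,9,1,0,1,1
39,2,9,11,1,0,1,1
39,3,11,20,1,0,1,1
39,4,20,26,1,0,1,1
39,5,26,30,1,0,1,1
39,6,30,45,0,0,1,1
40,1,0,18,1,0,1,1
40,2,18,48,0,0,1,1
41,1,0,49,0,0,1,3
42,1,0,35,1,0,3,1
42,2,35,51,0,0,3,1
43,1,0,17,1,0,1,7
43,2,17,53,0,0,1,7
44,1,0,3,1,0,3,1
44,2,3,15,1,0,3,1
44,3,15,46,1,0,3,1
44,4,46,51,1,0,3,1
44,5,51,53,1,0,3,1
45,1,0,59,0,0,1,1
46,1,0,2,1,0,3,2
46,2,2,15,1,0,3,2
46,3,15,24,1,0,3,2
46,4,24,30,1,0,3,2
46,5,30,34,1,0,3,2
46,6,34,39,1,0,3,2
46,7,39,43,1,0,3,2
46,8,43,49,1,0,3,2
46,9,49,52,1,0,3,2
46,10,52,61,0,0,3,2
47,1,0,5,1,0,1,3
47,2,5,14,1,0,1,3
47,3,14,19,1,0,1,3
47,4,19,27,1,0,1,3
47,5,27,41,1,0,1,3
47,6,41,64,0,0,1,3
48,1,0,2,1,0,2,3
48,2,2,8,1,0,2,3
48,3,8,12,1,0,2,3
48,4,12,13,1,0,2,3
48,5,13,17,1,0,2,3
48,6,17,21,1,0,2,3
48,7,21,33,1,0,2,3
48,8,33,49,1,0,2,3
48,9,49,64,0,0,2,3
81,1,0,1,0,1,1,3
82,1,0,1,0,1,1,1
83,1,0,5,1,1,8,1
84,1,0,9,0,1,1,2
85,1,0,10,0,1,1,1
86,1,0,13,0,1,1,1
87,1,0,3,1,1,2,6
87,2,3,14,0,1,2,6
88,1,0,1,1,1,5,3
88,2,1,3,1,1,5,3
88,3,3,5,1,1,5,3
88,4,5,7,1,1,5,3
88,5,7,10,1,1,5,3
88,6,10,17,0,1,5,3
89,1,0,18,0,1,5,1
90,1,0,17,1,1,1,3
90,2,17,18,0,1,1,3
91,1,0,2,1,1,5,1
91,2,2,19,0,1,5,1
92,1,0,17,1,1,1,1
92,2,17,19,1,1,1,1
92,3,19,21,0,1,1,1
93,1,0,22,0,1,1,1
94,1,0,25,0,1,1,3
95,1,0,25,0,1,1,5
96,1,0,25,0,1,1,1
97,1,0,6,1,1,1,1
97,2,6,12,1,1,1,1
97,3,12,13,1,1,1,1
97,4,13,26,0,1,1,1
98,1,0,6,1,1,1,1
98,2,6,27,0,1,1,1
99,1,0,2,1,1,2,1
99,2,2,29,0,1,2,1
100,1,0,26,1,1,8,3
100,2,26,35,1,1,8,3
100,3,35,36,0,1,8,3
101,1,0,38,0,1,1,1
102,1,0,22,1,1,1,1
102,2,22,23,1,1,1,1
102,3,23,27,1,1,1,1
102,4,27,32,1,1,1,1
102,5,32,39,0,1,1,1
103,1,0,4,1,1,6,1
103,2,4,16,1,1,6,1
103,3,16,23,1,1,6,1
103,4,23,27,1,1,6,1
103,5,27,33,1,1,6,1
103,6,33,36,1,1,6,1
103,7,36,37,1,1,6,1
103,8,37,39,0,1,6,1
104,1,0,24,1,1,3,1
104,2,24,26,1,1,3,1
104,3,26,29,1,1,3,1
104,4,29,40,1,1,3,1
105,1,0,41,0,1,3,2
106,1,0,41,0,1,1,1
107,1,0,1,1,1,1,1
107,2,1,27,1,1,1,1
107,3,27,43,0,1,1,1
108,1,0,44,0,1,1,1
109,1,0,2,1,1,6,1
109,2,2,20,1,1,6,1
109,3,20,23,1,1,6,1
109,4,23,27,1,1,6,1
109,5,27,38,1,1,6,1
109,6,38,44,0,1,6,1
110,1,0,45,0,1,1,2
111,1,0,2,1,1,1,4
111,2,2,46,0,1,1,4
112,1,0,46,0,1,1,4
113,1,0,49,0,1,3,3
114,1,0,50,0,1,1,1
115,1,0,4,1,1,4,1
115,2,4,24,1,1,4,1
115,3,24,47,1,1,4,1
115,4,47,50,0,1,4,1
116,1,0,54,0,1,3,4
117,1,0,38,1,1,2,1
117,2,38,54,0,1,2,1
118,1,0,59,0,1,1,3
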