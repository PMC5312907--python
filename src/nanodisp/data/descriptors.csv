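# provenance: SRW09=supplied,DipoleZ=supplied,piPC05=supplied,Ram=supplied,X0Av=supplied,ATS6m=supplied
id,SRW09,DipoleZ,piPC05,Ram,X0Av,ATS6m
1,702,2.225,30,3,0.632,6.731
2,0,-0.166,10,1,0.576,0.000
3,684,1.312,78,3,0.582,7.343
4,684,0.459,14,2,0.660,6.580
5,504,0.515,4,1,0.588,0.000
6,684,1.110,18,2,0.584,6.472
7,684,-1.214,8,2,0.648,2.583
8,684,-0.743,18,2,0.673,7.406
9,684,-1.345,10,2,0.595,2.215
10,504,-0.006,4,1,0.554,0.000
11,0,0.000,0,2,0.726,0.000
12,0,2.665,12,1,0.621,3.566
13,684,-0.590,22,2,0.681,7.797
14,0,0.000,0,0,0.521,0.000
15,0,1.192,63,2,0.583,6.898
16,0,0.000,0,0,0.649,0.000
17,0,0.000,0,1,0.528,0.000
18,0,0.001,2,0,0.707,5.869
19,0,0.887,0,0,0.610,0.000
20,504,0.454,4,1,0.623,0.000
21,0,0.000,52,2,0.611,0.703
22,0,0.000,0,1,0.727,0.000
23,0,-0.763,132,3,0.550,7.631
24,0,-1.142,0,1,0.756,0.000
25,0,1.892,10,1,0.635,0.000
26,0,0.000,44,1,0.627,1.401
27,0,0.000,5,0,0.595,6.923
28,0,0.000,0,0,0.521,0.000
29,0,-0.973,50,1,0.568,3.508
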