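id,name,conc_mg_ml,logc_exp,logc_cal,split
1,N-Cyclohexyl-pyrrolidinone,3.5,0.544,0.317,train
2,"1,3-Dimethyltetrahydro-2(1H)-pyrimidinone",0.65,-0.187,-0.617,test
3,1-Butylpyrrolidin-2-one,0.279,-0.554,-0.480,train
4,1-Benzylpyrrolidin-2-one,0.18,-0.745,-0.566,train
5,1-Methylpyrrolidin-2-one,0.116,-0.935,-0.972,test
6,3-(2-Oxo-1-pyrrolidinyl)propanenitrile,0.115,-0.939,-0.510,train
7,N-Ethyl-pyrrolidinone,0.101,-0.996,-1.200,train
8,N-Octyl-pyrrolidone,0.092,-1.036,-1.241,train
9,N-Vinyl-pyrrolidinone,0.084,-1.076,-1.459,train
10,Dimethyl-imidazolidinone,0.083,-1.080,-1.111,train
11,Dimethylacetamide,0.041,-1.387,-1.534,train
12,N-Formyl-piperidine,0.039,-1.409,-1.126,test
13,N-Dodecyl-pyrrolidone,0.03,-1.553,-1.157,train
14,Dimethylformamide,0.023,-1.638,-2.374,train
15,Benzyl acetate,0.0192,-1.717,-2.040,train
16,Propionitrile,0.015,-1.824,-1.850,train
17,Acrylic acid,0.0138,-1.860,-2.345,train
18,"2,2'-Thiodiethanol",0.0136,-1.866,-2.100,train
19,Ethanolamine,0.0133,-1.876,-1.424,test
20,Cyclopentanone,0.0129,-1.889,-1.757,test
21,Chlorophenol,0.012,-1.921,-2.064,test
22,Acetone,0.011,-1.959,-1.530,train
23,Benzyl benzoate,0.0109,-1.963,-2.160,train
24,Isopropyl alcohol,0.0105,-1.979,-2.038,train
25,Cyclohexanone,0.0068,-2.168,-2.330,test
26,Toluene,0.005,-2.301,-2.056,train
27,Triethyleneglycol,0.0037,-2.432,-2.647,train
28,Formamide,3.00e-4,-3.523,-2.374,train
29,Benzyl alcohol,2.79e-4,-3.554,-3.007,train
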