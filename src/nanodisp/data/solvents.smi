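1 O=C1CCCN1C1CCCCC1
2 O=C1N(C)CCCN1C
3 CCCCN1CCCC1=O
4 O=C1CCCN1Cc1ccccc1
5 CN1CCCC1=O
6 N#CCCN1CCCC1=O
7 CCN1CCCC1=O
8 CCCCCCCCN1CCCC1=O
9 C=CN1CCCC1=O
10 CN1CCN(C)C1=O
11 CC(=O)N(C)C
12 O=CN1CCCCC1
13 CCCCCCCCCCCCN1CCCC1=O
14 CN(C)C=O
15 CC(=O)OCc1ccccc1
16 CCC#N
17 C=CC(=O)O
18 OCCSCCO
19 NCCO
20 O=C1CCCC1
21 Oc1ccccc1Cl
22 CC(C)=O
23 O=C(OCc1ccccc1)c1ccccc1
24 CC(C)O
25 O=C1CCCCC1
26 Cc1ccccc1
27 OCCOCCOCCO
28 NC=O
29 OCc1ccccc1
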