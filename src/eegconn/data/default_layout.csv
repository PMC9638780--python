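id,label,ap_mm,ml_mm,hemisphere,region_class
0,M2-L1,3.9,-5.25,left,rostral
1,M2-L2,3.9,-1.75,left,rostral
2,M2-R1,3.9,1.75,right,rostral
3,M2-R2,3.9,5.25,right,rostral
4,M2-L3,2.6,-5.25,left,rostral
5,M2-L4,2.6,-1.75,left,rostral
6,M2-R3,2.6,1.75,right,rostral
7,M2-R4,2.6,5.25,right,rostral
8,M2-L5,1.3,-5.25,left,rostral
9,M2-L6,1.3,-1.75,left,rostral
10,M2-R5,1.3,1.75,right,rostral
11,M2-R6,1.3,5.25,right,rostral
12,S1Tr-L1,0.0,-5.25,left,middle
13,S1Tr-L2,0.0,-1.75,left,middle
14,S1Tr-R1,0.0,1.75,right,middle
15,S1Tr-R2,0.0,5.25,right,middle
16,S1Tr-L3,-1.3,-5.25,left,middle
17,S1Tr-L4,-1.3,-1.75,left,middle
18,S1Tr-R3,-1.3,1.75,right,middle
19,S1Tr-R4,-1.3,5.25,right,middle
20,S1Tr-L5,-2.6,-5.25,left,middle
21,S1Tr-L6,-2.6,-1.75,left,middle
22,S1Tr-R5,-2.6,1.75,right,middle
23,S1Tr-R6,-2.6,5.25,right,middle
24,V1-L1,-3.9,-5.25,left,caudal
25,V1-L2,-3.9,-1.75,left,caudal
26,V1-R1,-3.9,1.75,right,caudal
27,V1-R2,-3.9,5.25,right,caudal
28,V1-L3,-5.2,-5.25,left,caudal
29,V1-L4,-5.2,-1.75,left,caudal
30,V1-R3,-5.2,1.75,right,caudal
31,V1-R4,-5.2,5.25,right,caudal
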