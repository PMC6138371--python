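id,assign_C1,assign_C2,assign_C3,assign_C4,kde50_C1,kde50_C2,kde50_C3,kde50_C4,kde75_C1,kde75_C2,kde75_C3,kde75_C4
1RZ,100,0,0,0,23,76,1,0,41,52,8,0
1ST,0,100,0,0,0,0,100,0,0,0,98,2
1SU,4,96,0,0,73,27,0,0,76,24,0,0
1TQ,88,12,0,0,0,0,61,39,0,0,65,35
1TS,98,2,0,0,0,0,100,0,0,0,100,0
1UE,100,0,0,0,0,0,100,0,0,2,98,0
1UH,40,60,0,0,0,6,94,0,0,6,94,0
1UJ,78,22,0,0,5,61,34,0,4,57,39,0
1UY,100,0,0,0,0,0,81,19,4,73,23,0
1WG,100,0,0,0,9,32,60,0,10,29,62,0
1WH,0,100,0,0,97,3,0,0,73,26,1,0
1WW,32,68,0,0,91,9,0,0,57,21,21,0
1XR,100,0,0,0,2,48,51,0,1,28,72,0
1XT,86,14,0,0,57,39,4,0,54,28,18,0
1YA,0,100,0,0,89,5,5,0,89,8,3,0
1YD,0,100,0,0,41,58,1,0,29,64,7,0
1YW,100,0,0,0,0,4,96,0,0,5,95,0
1ZS,52,48,0,0,88,12,0,0,79,21,0,0
1ZV,100,0,0,0,15,83,2,0,22,61,17,0
2AA,34,56,0,0,0,0,79,21,0,0,73,27
2AI,56,44,0,0,0,22,78,0,0,23,75,2
2AL,12,88,0,0,0,13,87,0,0,15,68,17
2AR,88,12,0,0,12,18,69,0,17,15,68,0
2AZ,12,88,0,0,0,0,93,7,0,0,84,16
2BJ,100,0,0,0,1,4,94,0,2,4,94,0
2CT,100,0,0,0,15,34,51,0,12,27,62,0
2DC,0,100,0,0,73,27,0,0,76,23,1,0
2DF,2,98,0,0,1,1,98,0,16,13,70,1
3CX,100,0,0,0,20,2,78,0,9,1,89,1
3RD,0,100,0,0,74,26,0,0,68,21,11,0
3RN,0,100,0,0,0,0,100,0,0,0,100,0
3ST,0,100,0,0,0,0,100,0,0,0,100,0
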