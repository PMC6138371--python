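id,assign_C1,assign_C2,assign_C3,assign_C4,assign_C5,kde50_C1,kde50_C2,kde50_C3,kde50_C4,kde50_C5,kde75_C1,kde75_C2,kde75_C3,kde75_C4,kde75_C5
1RZ,0,0,100,0,0,0,78,22,0,0,0,58,39,4,0
1ST,0,100,0,0,0,0,0,0,59,41,0,0,0,51,49
1SU,0,0,100,0,0,0,30,70,0,0,0,26,74,0,0
1TQ,0,0,100,0,0,0,0,0,12,88,0,0,0,21,79
1TS,0,0,100,0,0,0,0,0,1,99,0,0,0,24,76
1UE,0,0,100,0,0,0,3,0,97,0,0,3,0,79,18
1UH,0,0,100,0,0,0,6,0,94,0,0,7,0,83,10
1UJ,0,0,100,0,0,0,0,5,31,63,0,0,4,33,63
1UY,0,0,100,0,0,0,11,0,53,36,0,15,1,47,37
1WG,0,0,100,0,0,0,39,7,53,0,1,32,10,58,0
1WH,0,100,0,0,0,0,2,98,0,0,0,25,75,0,0
1WW,0,0,100,0,0,3,14,83,0,0,5,30,50,14,0
1XR,0,0,100,0,0,0,63,0,37,0,0,36,0,44,21
1XT,0,0,100,0,0,1,37,60,2,0,3,29,53,15,0
1YA,0,18,82,0,0,0,21,79,0,0,1,15,84,0,0
1YD,0,100,0,0,0,38,59,3,0,0,63,33,3,1,0
1YW,0,0,100,0,0,0,4,0,85,10,0,7,0,72,21
1ZS,0,0,100,0,0,8,20,72,0,0,12,24,63,0,0
1ZV,0,0,100,0,0,0,90,10,0,0,0,77,18,5,0
2AA,0,0,100,0,0,0,0,0,21,79,0,0,0,26,74
2AI,0,0,100,0,0,0,16,0,36,47,0,20,0,32,48
2AL,0,0,100,0,0,0,17,0,77,6,0,18,0,41,40
2AR,0,0,100,0,0,4,20,9,67,0,4,20,11,59,6
2AZ,0,0,100,0,0,0,0,0,45,55,0,0,0,45,55
2BJ,2,0,98,0,0,0,30,0,70,0,0,21,2,73,4
2CT,0,0,100,0,0,0,41,15,44,0,1,30,12,48,9
2DC,0,18,82,0,0,0,30,70,0,0,0,25,75,0,0
2DF,0,0,100,0,0,0,26,0,73,1,0,31,0,55,13
3CX,0,0,100,0,0,0,38,14,48,0,0,17,8,69,6
3RD,0,0,100,0,0,0,26,74,0,0,0,29,66,5,0
3RN,0,100,0,0,0,0,0,0,100,0,0,0,0,100,0
3ST,0,100,0,0,0,0,2,0,92,6,0,1,0,69,30
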