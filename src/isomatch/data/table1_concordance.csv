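id,lat,lon,kde_km2_50,kde_km2_75,kde_cells_50,kde_cells_75,cn_cells_11,cn_cells_31,hcn_cells_11,hcn_cells_31,ov_hcn_cells_50,ov_hcn_cells_75,ov_hcn_pct_50,ov_hcn_pct_75,ov_cn_cells_50,ov_cn_cells_75,ov_cn_pct_50,ov_cn_pct_75
1RZ,4.0,14.6,171826,348808,133,269,828,1420,312,813,0.0,3.0,0.0,1.1,6.0,66.0,4.5,24.5
1ST,9.2,-2.9,127633,281490,98,217,1671,3143,770,1578,0.0,1.0,0.0,0.5,0.0,11.0,0.0,5.1
1SU,-0.4,14.2,133563,268400,103,207,866,1824,400,1040,0.0,21.0,0.0,10.1,7.0,71.0,6.8,34.3
1TQ,13.5,10.3,183776,444172,142,343,1073,1771,415,1006,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1TS,12.6,-8.0,124394,324231,96,250,341,1093,202,726,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1UE,9.5,7.4,91977,201018,71,155,920,1556,405,1011,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1UH,8.6,6.6,139026,329324,107,254,1169,2004,194,462,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1UJ,10.2,16.0,269300,522239,208,403,1147,1931,560,1241,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1UY,10.1,17.1,278742,551148,215,425,1021,1688,584,1160,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1WG,6.4,10.5,155518,322219,120,249,914,1541,199,464,0.0,0.0,0.0,0.0,0.0,5.0,0.0,2.0
1WH,0.9,13.0,102288,297575,79,230,1636,3434,620,1289,0.0,0.0,0.0,0.0,0.0,21.0,0.0,9.1
1WW,1.5,8.7,139341,458723,108,354,1031,1789,175,414,0.0,0.0,0.0,0.0,17.0,84.0,15.8,23.7
1XR,7.0,10.6,115981,323817,89,250,866,1466,197,515,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1XT,3.6,11.5,171685,344246,132,266,845,1494,225,626,0.0,3.0,0.0,1.1,14.0,63.0,10.6,23.7
1YA,-1.3,8.9,173642,420043,134,324,1295,2526,647,1363,0.0,12.0,0.0,3.7,18.0,78.0,13.4,24.1
1YD,-27.9,25.6,125560,233820,97,180,1401,2684,929,1899,7.0,2.0,7.2,1.1,4.0,1.0,4.1,0.6
1YW,7.7,7.3,202535,414928,156,320,166,855,113,507,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
1ZS,0.6,6.3,101523,242870,78,187,996,1710,227,570,0.0,0.0,0.0,0.0,8.0,37.0,10.2,19.7
1ZV,3.3,15.6,160011,307053,123,237,790,1397,267,748,0.0,0.0,0.0,0.0,3.0,27.0,2.4,11.4
2AA,12.7,6.2,157142,329983,121,255,1114,1934,110,282,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
2AI,13.1,-10.4,294337,631533,227,487,592,1349,201,520,0.0,11.0,0.0,2.3,0.0,0.0,0.0,0.0
2AL,7.6,13.2,147322,456900,114,353,1177,2001,470,1055,0.0,3.0,0.0,0.9,0.0,1.0,0.0,0.3
2AR,6.3,9.1,198118,404295,153,312,134,888,148,592,0.0,0.0,0.0,0.0,0.0,1.0,0.0,0.3
2AZ,9.1,15.9,111478,212401,86,164,1253,2321,643,1377,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
2BJ,7.4,-0.3,111544,220143,86,170,968,1662,225,476,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
2CT,5.4,7.8,124339,323513,96,250,909,1537,407,963,2.0,16.0,2.1,6.4,1.0,6.0,1.0,2.4
2DC,-3.6,14.0,149296,340756,115,263,1042,2327,523,1194,0.0,17.0,0.0,6.5,16.0,92.0,13.9,35.0
2DF,7.2,18.4,156047,498641,120,385,1189,2082,138,336,0.0,0.0,0.0,0.0,0.0,1.0,0.0,0.3
3CX,4.9,-4.5,60807,210245,47,162,767,1374,464,975,0.0,1.0,0.0,0.6,0.0,0.0,0.0,0.0
3RD,-2.8,14.5,95104,343880,73,265,988,2200,437,1043,0.0,14.0,0.0,5.3,20.0,114.0,27.3,43.0
3RN,-25.0,20.6,105973,250801,82,194,1567,3235,1142,2412,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
3ST,7.9,-2.7,96932,204126,75,158,1877,3448,915,1841,0.0,9.0,0.0,5.7,5.0,20.0,6.7,12.7
mean,,,149274,345729,115,267,1017,1928,415,953,0.3,3.5,0.3,1.4,3.7,21.8,3.6,8.5
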