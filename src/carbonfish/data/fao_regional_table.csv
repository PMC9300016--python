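area,name,poc_export,export_rank,fishing_intensity,fishing_rank,catch_pct,main_gear,main_groups
18,Arctic Sea,65.09,8,0.02,19,0,"T (36), PS (32)","GF (85)"
21,NW Atlantic,98.98,2,1.14,3,2,"D (31), T (23)","BC (20), B (12), SP (21)"
27,NE Atlantic,95.45,3,1.85,2,11,"T (72)","SP (38), GF (13)"
31,Central W Atlantic,47.95,14,0.32,12,2,"PS (46), T (23)","SP (36), UF (10), B (5)"
34,Central E Atlantic,83.80,4,1.01,4,6,"PS (39), T (30)","SP (54)"
37,Mediterranean,60.62,10,2.75,1,2,"T (38), PS (29)","SP (44), UF (4), B (4)"
41,SW Atlantic,75.45,6,0.53,10,2,"T (70)","S (21), GF (22), BC (5), DF (4)"
47,SE Atlantic,73.75,7,0.42,11,2,"T (39), PS (31)","SP (34), GF (19)"
48,Antarctic Atlantic,41.04,16,0.05,16,0,"T (99)","PC (99)"
51,W Indian,57.69,11,0.61,8,6,"T (38), SG (22)","UF (14), SP (13), LP (12), GF (8), DF (3), PC (3)"
57,E Indian,48.70,13,0.22,14,8,"T (33), SG (31)","UF (30), SP (12), LP (3), PC (2), UC (2), GF (2)"
58,Antarctic Indian,39.78,17,0.05,17,0,"LL (95)","DF (79)"
61,NW Pacific,80.57,5,0.92,5,27,"T (49), UG (13)","GF (15), SP (14), UF (13), UM (3), PC (3), S (2), LP (2)"
67,NE Pacific,102.58,1,0.64,7,4,"T (77)","GF (54)"
71,Central W Pacific,39.60,18,0.87,6,15,"T (45), PS (13)","UF (23), LP (17), SP (8), S (2)"
77,Central E Pacific,46.44,15,0.56,9,2,"PS (56)","SP (42), LP (9)"
81,SW Pacific,49.27,12,0.22,15,1,"PS (58)","DF (24), UF (11), SP (14), S (5)"
87,SE Pacific,64.37,9,0.32,13,12,"PS (78)","SP (57)"
88,Antarctic Pacific,33.83,19,0.02,18,0,"LL (100)","DF (95)"
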