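country,score_2010,rank_2010,score_2020,rank_2020
AG,0.5085,7,0.4290,11
AR,0.2041,30,0.3830,15
BB,0.5572,4,0.5267,6
BZ,0.2559,25,0.3869,13
BO,0.1940,32,0.1772,35
BR,0.2929,19,0.5192,8
CA,0.5939,3,0.5557,2
CL,0.3262,16,0.4703,9
CO,0.4405,12,0.3038,20
CR,0.5543,5,0.2430,28
CU,0.5445,6,0.2623,27
DM,0.4163,13,0.2019,30
DO,0.3013,18,0.2011,32
EC,0.2724,22,0.3950,12
SV,0.2373,27,0.2686,25
GD,0.4717,11,0.2149,29
GT,0.2768,21,0.2872,23
GY,0.1893,34,0.2955,21
HT,0.1766,35,0.1852,33
HN,0.3076,17,0.3390,19
JM,0.2092,29,0.2649,26
MX,0.1954,31,0.3766,16
NI,0.2682,23,0.3849,14
PA,0.4835,9,0.3473,18
PY,0.3378,15,0.2927,22
PE,0.2204,28,0.1838,34
LC,0.2391,26,0.2013,31
VC,0.7107,1,0.5496,3
KN,0.4864,8,0.4490,10
SR,0.4135,14,0.2760,24
BS,0.2631,24,0.5287,5
TT,0.4807,10,0.5351,4
US,0.6219,2,0.6161,1
UY,0.1917,33,0.5235,7
VE,0.2778,20,0.3569,17
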