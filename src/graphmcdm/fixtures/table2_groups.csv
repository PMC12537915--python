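country,group_2010,group_2020
AG,2,1
AR,0,5
BB,2,1
BZ,0,5
BO,4,2
BR,5,5
CA,1,4
CL,1,0
CO,5,0
CR,2,3
CU,2,0
DM,2,5
DO,5,5
EC,4,0
SV,2,5
GD,3,1
GT,1,0
GY,1,2
HT,4,5
HN,1,5
JM,3,1
MX,5,5
NI,4,0
PA,5,2
PY,1,2
PE,0,2
LC,5,3
VC,3,1
KN,3,1
SR,1,2
BS,4,4
TT,2,1
US,2,4
UY,0,0
VE,5,5
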