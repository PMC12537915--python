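country,waspas_2010,topsis_2010,vikor_2010,waspas_2020,topsis_2020,vikor_2020
AG,5,4,3,1,1,2
AR,31,31,30,22,21,17
BB,6,3,1,2,2,1
BZ,33,34,34,23,27,25
BO,32,32,31,33,34,33
BR,17,17,16,13,19,18
CA,13,14,13,12,15,11
CL,23,22,18,19,23,21
CO,21,19,20,30,33,32
CR,10,11,11,32,17,35
CU,12,12,12,11,10,10
DM,8,8,9,14,8,8
DO,16,15,22,15,12,14
EC,27,29,27,25,32,29
SV,11,13,14,20,14,16
GD,3,5,2,6,5,3
GT,25,27,26,24,31,27
GY,22,21,21,27,26,23
HT,30,28,29,31,30,31
HN,20,24,24,21,28,26
JM,2,2,6,8,6,5
MX,24,23,23,16,20,20
NI,28,26,28,17,18,24
PA,15,16,15,18,25,28
PY,26,25,25,29,29,30
PE,34,33,33,35,35,34
LC,14,9,8,34,16,15
VC,4,6,4,3,3,4
KN,1,1,5,4,7,7
SR,19,18,17,26,22,19
BS,35,35,35,10,13,12
TT,7,7,7,5,4,6
US,9,10,10,7,9,9
UY,29,30,32,9,11,13
VE,18,20,19,28,24,22
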