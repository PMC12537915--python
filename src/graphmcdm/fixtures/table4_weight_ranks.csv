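country,dcritic_2010,entropy_2010,merec_2010,dcritic_2020,entropy_2020,merec_2020
AG,5,1,2,1,8,1
AR,31,21,25,22,16,20
BB,6,3,4,2,12,2
BZ,33,22,34,23,25,27
BO,32,35,33,33,32,34
BR,17,12,19,13,18,5
CA,13,10,10,12,7,3
CL,23,20,28,19,23,22
CO,21,18,24,30,5,26
CR,10,11,12,32,19,14
CU,12,15,14,11,10,13
DM,8,7,11,14,24,11
DO,16,13,16,15,26,17
EC,27,31,18,25,28,28
SV,11,23,13,20,29,21
GD,3,6,6,6,1,8
GT,25,19,30,24,21,32
GY,22,34,27,27,27,25
HT,30,33,32,31,34,33
HN,20,25,17,21,22,31
JM,2,9,5,8,20,12
MX,24,16,26,16,13,18
NI,28,26,31,17,17,24
PA,15,17,20,18,11,23
PY,26,27,29,29,15,29
PE,34,32,35,35,33,35
LC,14,28,8,34,35,16
VC,4,4,3,3,9,9
KN,1,2,1,4,4,10
SR,19,29,21,26,30,19
BS,35,30,22,10,6,7
TT,7,8,9,5,3,6
US,9,5,7,7,2,4
UY,29,14,15,9,14,15
VE,18,24,23,28,31,30
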