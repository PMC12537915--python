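country,fq_2010,ds_2010,ve_2010,fq_2020,ds_2020,ve_2020
AG,7,12,5,11,16,6
AR,30,33,28,15,13,13
BB,4,6,2,6,9,2
BZ,25,22,19,13,12,12
BO,32,32,33,35,35,33
BR,19,23,27,8,5,10
CA,3,2,4,2,1,3
CL,16,16,16,9,8,11
CO,12,8,13,20,20,22
CR,5,4,9,28,27,26
CU,6,5,10,27,25,29
DM,13,14,11,30,32,27
DO,18,17,15,32,31,34
EC,22,19,21,12,15,18
SV,27,25,29,25,28,31
GD,11,13,6,29,30,25
GT,21,20,18,23,23,21
GY,34,29,35,21,19,23
HT,35,34,34,33,29,35
HN,17,18,20,19,21,20
JM,29,35,25,26,26,16
MX,31,31,31,16,14,14
NI,23,21,22,14,11,17
PA,9,7,12,18,18,15
PY,15,15,17,22,22,24
PE,28,30,32,34,33,32
LC,26,26,24,31,34,30
VC,1,1,1,3,7,5
KN,8,11,7,10,10,8
SR,14,10,14,24,24,28
BS,24,28,23,5,3,7
TT,10,9,8,4,4,4
US,2,3,3,1,2,1
UY,33,27,30,7,6,9
VE,20,23,26,17,17,19
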