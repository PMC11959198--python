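country,min_offset_hours,max_offset_hours
US,-10,-4
CA,-8,-3.5
MX,-8,-5
BR,-5,-2
VE,-4,-4
GB,0,1
IE,0,1
FR,1,2
DE,1,2
ES,1,2
NG,1,1
GH,0,0
CI,0,0
SN,0,0
CM,1,1
KE,3,3
ZA,2,2
EG,2,3
IN,5.5,5.5
PK,5,5
BD,6,6
PH,8,8
CN,8,8
JP,9,9
AU,8,11
NZ,12,13
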