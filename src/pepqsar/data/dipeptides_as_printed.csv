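sequence,activity,z11,z12,z13,z21,z22,z23
AA,3.21,0.07,-1.73,0.09,0.07,-1.73,0.09
AW,5,0.07,-1.73,0.09,-4.75,3.65,0.85
DG,1.85,3.64,1.13,2.36,2.23,-5.36,0.3
GF,3.2,2.23,-5.36,0.3,-4.92,1.3,0.45
GP,3.35,2.23,-5.36,0.3,-1.22,0.88,2.23
GR,2.49,2.23,-5.36,0.3,2.88,2.52,-3.44
GW,4.52,2.23,-5.36,0.3,-4.75,3.65,0.85
GY,3.68,2.23,-5.36,0.3,-1.39,2.32,0.01
IF,3.03,-4.44,-1.68,-1.03,-4.92,1.3,0.45
IW,5.7,-4.44,-1.68,-1.03,-4.75,3.65,0.85
IY,5.43,-4.44,-1.68,-1.03,-1.39,2.32,0.01
RF,3.64,2.88,2.52,-3.44,-4.92,1.3,0.45
RP,1.1818,2.88,2.52,-3.44,-1.22,0.88,2.23
VG,2.96,-2.69,-2.53,-1.29,2.23,-5.36,0.3
VW,1.6,-2.69,-2.53,-1.29,-4.75,3.65,0.85
VY,4.66,-2.69,-2.53,-1.29,-1.39,2.32,0.01
YG,2.7,-1.39,2.32,0.01,2.23,-5.36,0.3
RW,4.8,2.88,2.52,-3.44,-4.75,3.65,0.85
AY,4.28,-2.69,-2.53,-1.29,-4.92,1.3,0.45
RP,3.89,-4.44,-1.68,-1.03,-1.22,0.88,2.23
AF,3.72,0.07,-1.73,0.09,-4.92,1.3,0.45
AP,3.64,0.07,-1.73,0.09,-1.22,0.88,2.23
VP,3.38,-2.69,-2.53,-1.29,-1.22,0.88,2.23
IG,2.92,-4.44,-1.68,-1.03,2.23,-5.36,0.3
GI,2.92,2.23,-5.36,0.3,-4.44,-1.68,-1.03
GM,2.85,2.23,-5.36,0.3,-2.49,-0.27,-0.41
GA,2.7,2.23,-5.36,0.3,0.07,-1.73,0.09
GL,2.6,2.23,-5.36,0.3,-4.19,-1.03,-0.98
AG,2.6,0.07,-1.73,0.09,2.23,-5.36,0.3
GH,2.51,2.23,-5.36,0.3,2.41,1.74,1.11
KG,2.49,2.84,1.41,-3.14,2.23,-5.36,0.3
FG,2.43,-4.92,1.3,0.45,2.23,-5.36,0.3
GS,2.42,2.23,-5.36,0.3,1.96,-1.63,0.57
GV,2.34,2.23,-5.36,0.3,-2.69,-2.53,-1.29
MG,2.32,-2.49,-0.27,-0.41,2.23,-5.36,0.3
GK,2.27,2.23,-5.36,0.3,2.84,1.41,-3.14
GE,2.27,2.23,-5.36,0.3,3.08,0.39,-0.07
GT,2.24,2.23,-5.36,0.3,0.92,-2.09,-1.4
WG,2.23,-4.75,3.65,0.85,2.23,-5.36,0.3
HG,2.2,2.41,1.74,1.11,2.23,-5.36,0.3
GQ,2.15,2.23,-5.36,0.3,2.18,0.53,-1.14
GG,2.14,2.23,-5.36,0.3,2.23,-5.36,0.3
QG,2.13,2.18,0.53,-1.14,2.23,-5.36,0.3
SG,2.07,1.96,-1.63,0.57,2.23,-5.36,0.3
LG,2.06,-4.19,-1.03,-0.98,2.23,-5.36,0.3
GD,2.04,2.23,-5.36,0.3,3.64,1.13,2.36
TG,2,0.92,-2.09,-1.4,2.23,-5.36,0.3
EG,2,3.08,0.39,-0.07,2.23,-5.36,0.3
PG,1.77,-1.22,0.88,2.23,2.23,-5.36,0.3
LA,3.51,-4.19,-1.03,-0.98,0.07,-1.73,0.09
KA,3.42,2.84,1.41,-3.14,0.07,-1.73,0.09
RA,3.34,2.88,2.52,-3.44,0.07,-1.73,0.09
YA,3.34,-1.39,2.32,0.01,0.07,-1.73,0.09
FR,3.04,-4.92,1.3,0.45,2.88,2.52,-3.44
HL,2.49,2.41,1.74,1.11,-4.19,-1.03,-0.98
DA,2.42,3.64,1.13,2.36,0.07,-1.73,0.09
EA,2,3.08,0.39,-0.07,0.07,-1.73,0.09
DM,2.7782,3.64,1.13,2.36,-2.49,-0.27,-0.41
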