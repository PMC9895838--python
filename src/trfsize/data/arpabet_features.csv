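phoneme,sonorant,obstruent,voiced,back,front,low,high,dorsal,coronal,labial,syllabic,plosive,fricative,nasal
AA,1,0,1,1,0,1,0,0,0,0,1,0,0,0
AE,1,0,1,0,1,1,0,0,0,0,1,0,0,0
AH,1,0,1,0,0,0,0,0,0,0,1,0,0,0
AO,1,0,1,1,0,1,0,0,0,0,1,0,0,0
AW,1,0,1,1,0,1,0,0,0,0,1,0,0,0
AY,1,0,1,0,1,1,0,0,0,0,1,0,0,0
B,0,1,1,0,0,0,0,0,0,1,0,1,0,0
CH,0,1,0,0,0,0,0,0,1,0,0,1,1,0
D,0,1,1,0,0,0,0,0,1,0,0,1,0,0
DH,0,1,1,0,0,0,0,0,1,0,0,0,1,0
EH,1,0,1,0,1,0,0,0,0,0,1,0,0,0
ER,1,0,1,0,0,0,0,0,0,0,1,0,0,0
EY,1,0,1,0,1,0,0,0,0,0,1,0,0,0
F,0,1,0,0,0,0,0,0,0,1,0,0,1,0
G,0,1,1,0,0,0,0,1,0,0,0,1,0,0
HH,0,1,0,0,0,0,0,0,0,0,0,0,1,0
IH,1,0,1,0,1,0,1,0,0,0,1,0,0,0
IY,1,0,1,0,1,0,1,0,0,0,1,0,0,0
JH,0,1,1,0,0,0,0,0,1,0,0,1,1,0
K,0,1,0,0,0,0,0,1,0,0,0,1,0,0
L,1,0,1,0,0,0,0,0,1,0,0,0,0,0
M,1,0,1,0,0,0,0,0,0,1,0,0,0,1
N,1,0,1,0,0,0,0,0,1,0,0,0,0,1
NG,1,0,1,0,0,0,0,1,0,0,0,0,0,1
OW,1,0,1,1,0,0,0,0,0,0,1,0,0,0
OY,1,0,1,1,0,0,0,0,0,0,1,0,0,0
P,0,1,0,0,0,0,0,0,0,1,0,1,0,0
R,1,0,1,0,0,0,0,0,1,0,0,0,0,0
S,0,1,0,0,0,0,0,0,1,0,0,0,1,0
SH,0,1,0,0,0,0,0,0,1,0,0,0,1,0
T,0,1,0,0,0,0,0,0,1,0,0,1,0,0
TH,0,1,0,0,0,0,0,0,1,0,0,0,1,0
UH,1,0,1,1,0,0,1,0,0,0,1,0,0,0
UW,1,0,1,1,0,0,1,0,0,0,1,0,0,0
V,0,1,1,0,0,0,0,0,0,1,0,0,1,0
W,1,0,1,1,0,0,1,1,0,1,0,0,0,0
Y,1,0,1,0,1,0,1,1,0,0,0,0,0,0
Z,0,1,1,0,0,0,0,0,1,0,0,0,1,0
ZH,0,1,1,0,0,0,0,0,1,0,0,0,1,0
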