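country,continent
US,americas
CA,americas
BR,americas
MX,americas
AR,americas
CL,americas
CO,americas
PE,americas
FR,europe
DE,europe
GB,europe
IT,europe
ES,europe
NL,europe
SE,europe
CH,europe
BE,europe
PT,europe
PL,europe
DK,europe
NO,europe
FI,europe
IE,europe
AT,europe
GR,europe
CZ,europe
JP,asia
CN,asia
KR,asia
IN,asia
TH,asia
TW,asia
SG,asia
MY,asia
PH,asia
VN,asia
ID,asia
HK,asia
AU,oceania
NZ,oceania
IL,middle_east
SA,middle_east
AE,middle_east
TR,middle_east
IR,middle_east
IQ,middle_east
JO,middle_east
LB,middle_east
ZA,africa
NG,africa
KE,africa
MA,africa
TN,africa
DZ,africa
EG,africa
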