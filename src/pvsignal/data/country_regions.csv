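country,region
DZ,Africa
AO,Africa
BJ,Africa
BW,Africa
BF,Africa
BI,Africa
CM,Africa
CV,Africa
CF,Africa
TD,Africa
KM,Africa
CG,Africa
CD,Africa
CI,Africa
DJ,Africa
EG,Africa
GQ,Africa
ER,Africa
SZ,Africa
ET,Africa
GA,Africa
GM,Africa
GH,Africa
GN,Africa
GW,Africa
KE,Africa
LS,Africa
LR,Africa
LY,Africa
MG,Africa
MW,Africa
ML,Africa
MR,Africa
MU,Africa
MA,Africa
MZ,Africa
NA,Africa
NE,Africa
NG,Africa
RE,Africa
RW,Africa
ST,Africa
SN,Africa
SC,Africa
SL,Africa
SO,Africa
ZA,Africa
SS,Africa
SD,Africa
TZ,Africa
TG,Africa
TN,Africa
UG,Africa
YT,Africa
ZM,Africa
ZW,Africa
AF,Asia
AM,Asia
AZ,Asia
BH,Asia
BD,Asia
BT,Asia
BN,Asia
KH,Asia
CN,Asia
CY,Asia
GE,Asia
HK,Asia
IN,Asia
ID,Asia
IR,Asia
IQ,Asia
IL,Asia
JP,Asia
JO,Asia
KZ,Asia
KW,Asia
KG,Asia
LA,Asia
LB,Asia
MO,Asia
MY,Asia
MV,Asia
MN,Asia
MM,Asia
NP,Asia
KP,Asia
OM,Asia
PK,Asia
PS,Asia
PH,Asia
QA,Asia
SA,Asia
SG,Asia
KR,Asia
LK,Asia
SY,Asia
TW,Asia
TJ,Asia
TH,Asia
TL,Asia
TR,Asia
TM,Asia
AE,Asia
UZ,Asia
VN,Asia
YE,Asia
AL,Europe
AD,Europe
AT,Europe
BY,Europe
BE,Europe
BA,Europe
BG,Europe
HR,Europe
CZ,Europe
DK,Europe
EE,Europe
FO,Europe
FI,Europe
FR,Europe
DE,Europe
GI,Europe
GR,Europe
GG,Europe
HU,Europe
IS,Europe
IE,Europe
IM,Europe
IT,Europe
JE,Europe
XK,Europe
LV,Europe
LI,Europe
LT,Europe
LU,Europe
MT,Europe
MD,Europe
MC,Europe
ME,Europe
NL,Europe
MK,Europe
NO,Europe
PL,Europe
PT,Europe
RO,Europe
RU,Europe
SM,Europe
RS,Europe
SK,Europe
SI,Europe
ES,Europe
SE,Europe
CH,Europe
UA,Europe
GB,Europe
VA,Europe
AI,North America
AG,North America
AW,North America
BS,North America
BB,North America
BZ,North America
BM,North America
BQ,North America
CA,North America
CR,North America
CU,North America
CW,North America
DM,North America
DO,North America
SV,North America
GL,North America
GD,North America
GP,North America
GT,North America
HT,North America
HN,North America
JM,North America
KY,North America
MQ,North America
MX,North America
MS,North America
NI,North America
PA,North America
PR,North America
KN,North America
LC,North America
VC,North America
SX,North America
TC,North America
TT,North America
US,North America
VG,North America
VI,North America
AS,Oceania
AU,Oceania
CK,Oceania
FJ,Oceania
PF,Oceania
GU,Oceania
KI,Oceania
MH,Oceania
FM,Oceania
NR,Oceania
NC,Oceania
NZ,Oceania
NU,Oceania
MP,Oceania
PW,Oceania
PG,Oceania
WS,Oceania
SB,Oceania
TO,Oceania
TV,Oceania
VU,Oceania
WF,Oceania
AR,South America
BO,South America
BR,South America
CL,South America
CO,South America
EC,South America
FK,South America
GF,South America
GY,South America
PY,South America
PE,South America
SR,South America
UY,South America
VE,South America
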