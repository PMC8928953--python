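# DPP-IV inhibitory fragment library: union of the fragments annotated
# in the dry-cured pork loin peptide survey tables (WSF and SSF), with
# the tripeptide stored as PPL (the only reading consistent with the
# annotated positions 4-6 of FKRPPL and its occurrence count).
# activity: DPP-IV inhibitor
AA
AD
AE
AG
AL
AP
AV
DN
DP
DQ
DR
EG
EH
EI
EK
EP
ES
EV
FA
FQ
FR
GE
GF
GG
GH
GI
GL
GP
GV
HD
HL
HP
HS
IA
IH
II
IL
IN
IP
IQ
KE
KP
KR
KV
LH
LN
LP
LT
LV
MP
NA
NE
NL
NP
NV
PA
PF
PG
PH
PI
PK
PL
PM
PN
PP
PT
PV
QA
QD
QE
QF
QL
RA
RP
SF
SH
SI
SK
SL
SP
SV
TD
TE
TI
TK
TL
TP
VD
VE
VG
VI
VL
VN
VP
VS
VT
VV
WI
WT
YD
IPI
IPM
PPL
IIAP
PPPP
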