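# Elements assigned to class M (metals). One symbol per line; '#' starts a
# comment. Everything not listed here and not C/N/O/S maps to class X.
# Alkali / alkaline earth
LI
NA
K
RB
CS
FR
BE
MG
CA
SR
BA
RA
# Transition metals
SC
TI
V
CR
MN
FE
CO
NI
CU
ZN
Y
ZR
NB
MO
TC
RU
RH
PD
AG
CD
HF
TA
W
RE
OS
IR
PT
AU
HG
# Post-transition metals
AL
GA
IN
SN
TL
PB
BI
PO
# Lanthanides
LA
CE
PR
ND
PM
SM
EU
GD
TB
DY
HO
ER
TM
YB
LU
# Actinides
AC
TH
PA
U
NP
PU
AM
CM
BK
CF
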