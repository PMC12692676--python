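subclass,class
CAR,FA
FFA,FA
FAHFA,FA
NAE,FA
WE,FA
TG,GL
DG,GL
MG,GL
PC,GP
PC-O,GP
PC-P,GP
PE,GP
PE-O,GP
PE-P,GP
PS,GP
PS-O,GP
PI,GP
PG,GP
PA,GP
BMP,GP
CL,GP
MLCL,GP
LPC,GP
LPC-O,GP
LPE,GP
LPE-O,GP
LPE-P,GP
LPS,GP
LPI,GP
LPG,GP
LPA,GP
SM,SP
Cer,SP
CerP,SP
HexCer,SP
Hex2Cer,SP
Hex3Cer,SP
SHexCer,SP
SPH,SP
S1P,SP
CE,ST
ST,ST
SI,ST
CoQ,PR
VAE,PR
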