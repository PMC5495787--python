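resname,sidechain_sasa_A2
ALA,66.486
ARG,207.036
ASN,116.520
ASP,109.153
CYS,99.137
GLN,145.416
GLU,138.538
GLY,0.000
HIS,156.263
ILE,142.769
LEU,139.876
LYS,169.359
MET,159.833
PHE,177.925
PRO,95.459
SER,78.187
THR,105.438
TRP,218.738
TYR,188.271
VAL,119.301
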