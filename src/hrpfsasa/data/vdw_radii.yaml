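# Van der Waals radii (Å) per element, NACCESS-compatible united-atom set
# (Chothia 1976 values as used by NACCESS for heavy atoms).
# "*" is the fallback radius for unlisted elements (a warning is emitted).
H: 1.00   # parsed then discarded (united-atom convention ignores hydrogens)
C: 1.87
N: 1.65
O: 1.40
S: 1.85
P: 1.80
SE: 1.90
FE: 1.47
ZN: 1.39
MG: 1.18
CA: 1.74
"*": 1.80
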