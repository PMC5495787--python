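# Free amino acid reactivity toward hydroxyl radical, relative to proline
# (k/k_p, dimensionless). Compiled from aqueous radiolysis rate-constant
# data (Buxton et al. critical compilation, k in M^-1 s^-1, Pro = 6.5e8).
# Editable: the analysis treats this table as versioned configuration.
version: "buxton-1988-rel-pro-v1"
class_thresholds:
  high_min: 10.0   # k/k_p > 10  -> high
  poor_max: 4.0    # k/k_p < 4   -> poor; 4..10 -> moderate
values:
  CYS: 52.0
  TRP: 20.0
  TYR: 20.0
  MET: 13.0
  PHE: 10.6
  HIS: 7.4
  ARG: 5.4
  ILE: 2.8
  LEU: 2.6
  VAL: 1.3
  PRO: 1.0
  GLN: 0.83
  THR: 0.78
  LYS: 0.54
  SER: 0.49
  GLU: 0.35
  ALA: 0.12
  ASP: 0.12
  ASN: 0.075
  GLY: 0.026
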