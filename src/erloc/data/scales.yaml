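# Physicochemical property tables used by the amphiphilic pseudo-amino acid
# composition descriptors.  Raw (un-standardized) values per one-letter code;
# they are standardized to mean 0 / population sd 1 at load time.
#
# hydrophobicity: Tanford-derived scale as used in classic amphiphilic PseAAC.
# hydrophilicity: Hopp & Woods (1981) scale.
hydrophobicity:
  A: 0.62
  C: 0.29
  D: -0.90
  E: -0.74
  F: 1.19
  G: 0.48
  H: -0.40
  I: 1.38
  K: -1.50
  L: 1.06
  M: 0.64
  N: -0.78
  P: 0.12
  Q: -0.85
  R: -2.53
  S: -0.18
  T: -0.05
  V: 1.08
  W: 0.81
  Y: 0.26
hydrophilicity:
  A: -0.5
  C: -1.0
  D: 3.0
  E: 3.0
  F: -2.5
  G: 0.0
  H: -0.5
  I: -1.8
  K: 3.0
  L: -1.8
  M: -1.3
  N: 0.2
  P: 0.0
  Q: 0.2
  R: 3.0
  S: 0.3
  T: -0.4
  V: -1.5
  W: -3.4
  Y: -2.3
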