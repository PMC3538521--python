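# Atom-type contributions for the Crippen-style additive logP.
# Typing is a deliberately compact reconstruction of atomic-contribution logP
# schemes: ~20 element/environment classes, values loosely following published
# atomic contributions. The table is pluggable; the classifier lives in
# descriptors.py (_crippen_type). "wildcard" catches unclassifiable atoms.
contributions:
  C.sp3: 0.08          # aliphatic carbon, only C/H neighbors
  C.sp3.het: -0.20     # aliphatic carbon bonded to a heteroatom
  C.sp2: 0.08          # olefinic carbon
  C.sp2.carbonyl: -0.28
  C.sp: 0.13
  C.ar: 0.29           # aromatic carbon
  C.ar.het: 0.14       # aromatic carbon bonded to a heteroatom
  H.C: 0.123           # hydrogen on carbon
  H.het: -0.27         # hydrogen on N/O/S/P
  O.OH: -0.39
  O.ether: -0.10
  O.carbonyl: -0.12
  O.ar: 0.15
  O.minus: -1.33
  N.sp3: -0.80
  N.amide: -0.55
  N.sp2: -0.20
  N.ar: -0.26
  N.plus: -1.00
  S: 0.65
  P: 0.86
  F: 0.42
  Cl: 0.69
  Br: 0.85
  I: 0.89
  wildcard: 0.0
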