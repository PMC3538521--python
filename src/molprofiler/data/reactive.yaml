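# SMARTS encodings of the twelve reactive functional-group classes screened
# during curation.  The class names are fixed; the patterns are this package's
# own encodings and are editable.
patterns:
  aldehyde: ["[CX3H1]=O"]
  alkyl-halide: ["[CX4][Cl,Br,I]"]
  anhydride: ["[CX3](=O)[OX2][CX3]=O"]
  diazo: ["[#6]=[N+]=[N-]", "[#6][N+]#N"]
  dicarbonyl: ["[CX3](=O)[CX3]=O"]
  disulfide: ["[#16X2][#16X2]"]
  hydrazine-N-NH2: ["[NX3][NX3H2]"]
  isocyanate: ["[NX2]=C=O"]
  isothiocyanates: ["[NX2]=C=S"]
  peroxide: ["[OX2][OX2]"]
  quaternaryamine: ["[NX4+]"]
  acyl-halide: ["[CX3](=O)[F,Cl,Br,I]"]
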