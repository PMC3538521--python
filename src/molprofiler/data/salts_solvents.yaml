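# Counter-ion and solvent fragments stripped during curation (steps 2 and 4).
# Matched as whole disconnected fragments by canonical structure; the
# largest-fragment step is the safety net for anything not listed.
salts:
  - "[Na+]"
  - "[K+]"
  - "[Li+]"
  - "[Ca+2]"
  - "[Mg+2]"
  - "[Zn+2]"
  - "[NH4+]"
  - "[Cl-]"
  - "[Br-]"
  - "[I-]"
  - "[F-]"
  - "Cl"
  - "Br"
  - "I"
  - "[OH-]"
  - "O=S(=O)([O-])[O-]"
  - "OS(=O)(=O)O"
  - "[O-][N+](=O)[O-]"
  - "O[N+]([O-])=O"
  - "CC(=O)[O-]"
  - "CC(=O)O"
  - "OC(=O)C(F)(F)F"
  - "[O-]C(=O)C(F)(F)F"
  - "Cc1ccc(cc1)S(=O)(=O)O"
  - "Cc1ccc(cc1)S(=O)(=O)[O-]"
  - "CS(=O)(=O)O"
  - "CS(=O)(=O)[O-]"
  - "OC(=O)C=CC(=O)O"
  - "OC(=O)C(=O)O"
  - "OP(=O)(O)O"
solvents:
  - "O"
  - "CO"
  - "CCO"
  - "CC(C)O"
  - "CC(C)=O"
  - "CS(C)=O"
  - "CC#N"
  - "C1CCOC1"
  - "ClCCl"
  - "ClC(Cl)Cl"
  - "CCOCC"
  - "CCOC(C)=O"
  - "CN(C)C=O"
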