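# Bondi van der Waals radii and single-bond covalent radii (Angstrom) for the
# 2D additive surface-area scheme; probe radius for water-accessible areas.
probe_radius: 1.4
vdw:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  Cl: 1.75
  Br: 1.85
  I: 1.98
covalent:
  H: 0.31
  C: 0.76
  N: 0.71
  O: 0.66
  F: 0.57
  P: 1.07
  S: 1.05
  Cl: 1.02
  Br: 1.20
  I: 1.39
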