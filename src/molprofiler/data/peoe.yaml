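# Electronegativity polynomials chi(q) = a + b*q + c*q^2 for the iterative
# partial-equalization-of-orbital-electronegativity (PEOE) charge scheme,
# keyed by element and hybridization (sp3/sp2/sp).  Classic Gasteiger-Marsili
# sigma parameters (eV); the hydrogen cation electronegativity is special-cased.
iterations: 6
damping_base: 0.5
hydrogen_chi_plus: 20.02
parameters:
  H:   {sp3: [7.17, 0.64, -0.56], sp2: [7.17, 0.64, -0.56], sp: [7.17, 0.64, -0.56]}
  C:   {sp3: [7.98, 9.18, 1.88], sp2: [8.79, 9.32, 1.51], sp: [10.39, 9.45, 0.73]}
  N:   {sp3: [11.54, 10.82, 1.36], sp2: [12.87, 11.15, 0.85], sp: [15.68, 11.70, -0.27]}
  O:   {sp3: [14.18, 12.92, 1.39], sp2: [17.07, 13.79, 0.47], sp: [17.07, 13.79, 0.47]}
  F:   {sp3: [14.66, 13.85, 2.31], sp2: [14.66, 13.85, 2.31], sp: [14.66, 13.85, 2.31]}
  Cl:  {sp3: [11.00, 9.69, 1.35], sp2: [11.00, 9.69, 1.35], sp: [11.00, 9.69, 1.35]}
  Br:  {sp3: [10.08, 8.47, 1.16], sp2: [10.08, 8.47, 1.16], sp: [10.08, 8.47, 1.16]}
  I:   {sp3: [9.90, 7.96, 0.96], sp2: [9.90, 7.96, 0.96], sp: [9.90, 7.96, 0.96]}
  S:   {sp3: [10.14, 9.13, 1.38], sp2: [10.14, 9.13, 1.38], sp: [10.14, 9.13, 1.38]}
  P:   {sp3: [8.90, 8.24, 0.96], sp2: [8.90, 8.24, 0.96], sp: [8.90, 8.24, 0.96]}
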