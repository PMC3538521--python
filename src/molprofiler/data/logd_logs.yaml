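# Coefficients for the logD7.4 and logS surrogate models.
#
# logD7.4 = AlogP - sum(ionization penalty per group flagged ionized at pH 7.4)
# logS    = c0 + c1*AlogP + c2*MW + c3*N_rot + c4*N_aromatic
#
# Both are declared surrogates: simple, documented linear corrections whose
# coefficient tables can be swapped for published regression models.
logd_penalties:
  carboxylic_acid: 3.0   # pKa ~ 4, essentially fully ionized at pH 7.4
  sulfonic_acid: 5.0
  aliphatic_amine: 2.7   # pKa ~ 10, essentially fully protonated at pH 7.4
logs_coefficients:
  intercept: 0.8
  alogp: -0.70
  mw: -0.0062
  n_rot: -0.02
  n_aromatic: -0.03
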