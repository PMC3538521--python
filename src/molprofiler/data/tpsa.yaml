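# Fragment contributions (Angstrom^2) for the Ertl-style topological polar
# surface area over nitrogen/oxygen environments.  Keys are environment codes
# assigned by descriptors._tpsa_type; unmatched N/O environments fall back to
# the "N.fallback"/"O.fallback" values.
contributions:
  "N3": 3.24          # >N-  three single bonds, no H
  "N2=": 12.36        # =N-  two connections, one double
  "N1#": 23.79        # nitrile N
  "N3=": 11.68        # three connections incl. double (e.g. nitro N)
  "NH2": 26.02        # primary amine
  "NH": 12.03         # secondary amine
  "NH=": 23.85        # =NH
  "n.ar": 12.89       # aromatic N, two ring connections
  "n.arH": 15.79      # aromatic NH (pyrrole-type)
  "n.ar3": 4.41       # aromatic N, three connections
  "NH3+": 27.64
  "NH2+": 16.61
  "NH+": 4.44
  "N4+": 0.00
  "n.arH+": 14.14
  "n.ar+": 4.10
  "N.fallback": 12.00
  "OH": 20.23
  "O2": 9.23          # ether / ester sp3 oxygen
  "O=": 17.07
  "o.ar": 13.14
  "O-": 23.06
  "O.fallback": 15.00
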