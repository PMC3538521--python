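# Fragment sets for the synthetic compound generator: per class, weighted
# scaffolds and weighted substituents (substituent attachment atom = first
# atom of the SMILES).  The three classes emulate the qualitative property
# contrasts of drug-like, reagent-like and natural-product-like libraries:
#   druglike     — aromatic/heteroaromatic, nitrogen-rich, MW ~ 400
#   reagentlike  — small, few rings, reactive-prone groups, MW ~ 270
#   naturallike  — fused/bridged saturated ring systems, oxygen-rich,
#                  few rotatable bonds, stereocenter-rich
classes:
  druglike:
    mw_window: [370.0, 580.0]
    scaffolds:
      "c1ccccc1": 3.0
      "c1ccncc1": 2.0
      "c1cncnc1": 2.0
      "c1ccc2ccccc2c1": 1.0
      "c1ccc2[nH]ccc2c1": 2.0
      "c1ccc2ncccc2c1": 1.5
      "c1ncc2ccccc2n1": 1.0
      "c1ccc2[nH]cnc2c1": 1.0
      "C1CN(c2ccccc2)CCN1": 2.0
      "C1COCCN1c1ccccc1": 1.0
      "c1ccc(-c2ccccc2)cc1": 1.0
      "CN1C2CCC1CC2": 0.5
      "C1CN2CCC1CC2": 0.3
    substituents:
      "C": 3.0
      "CC": 1.0
      "OC": 2.0
      "N": 1.5
      "N(C)C": 2.0
      "NC(C)=O": 2.0
      "C(N)=O": 1.5
      "C(=O)N(C)C": 1.0
      "F": 1.5
      "Cl": 1.5
      "C#N": 1.0
      "S(C)(=O)=O": 1.0
      "c1ccccc1": 1.5
      "c1ccncc1": 1.0
      "O": 1.0
      "CN(C)C": 1.0
      "C=O": 0.3
      "CCl": 0.2
  reagentlike:
    mw_window: [240.0, 420.0]
    scaffolds:
      "c1ccccc1": 2.0
      "C1CCCCC1": 1.0
      "CCCC": 2.0
      "CC(C)C": 1.0
      "C1CCOC1": 1.0
      "CCOCC": 1.0
      "CCN": 1.0
      "CC=O": 1.0
      "CCC(C)=O": 1.0
    substituents:
      "C": 2.0
      "CC": 2.0
      "O": 1.0
      "OC": 1.0
      "N": 1.0
      "C=O": 1.5
      "CCl": 1.5
      "CBr": 0.5
      "C(=O)Cl": 1.0
      "N=C=O": 0.8
      "N=C=S": 0.4
      "OOC": 0.5
      "C(=O)C=O": 0.5
      "SSC": 0.5
      "NN": 0.5
      "Br": 1.0
      "Cl": 1.0
      "C(=O)OC": 1.0
      "C(=O)O": 0.8
  naturallike:
    mw_window: [350.0, 580.0]
    scaffolds:
      "C1CCC2CCCCC2C1": 2.0
      "C1CC2CCC1C2": 2.0
      "C1C2CC3CC1CC(C2)C3": 1.5
      "C1CC2CCC1CC2": 1.5
      "OCC1OC(O)C(O)C(O)C1O": 2.0
      "OCC1OC(O)C(O)C1O": 1.0
      "C1CCC2C(C1)CCC1C2CCC2CCCCC21": 1.5
      "CC1CCC2CC(C)CCC2C1": 1.0
      "O=C1CCCO1": 1.0
      "C1CCCCC1": 1.0
    substituents:
      "O": 5.0
      "OC": 0.8
      "C": 2.5
      "OC(C)=O": 0.6
      "CO": 0.8
      "C(C)C": 0.5
      "CC=C(C)C": 0.3
      "C=C": 0.3
      "C(=O)O": 0.3
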