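# molprofiler

Property profiling and drug-likeness screening of compound libraries from
2D molecular structure.

Early drug discovery triages large screening collections with simple
property-based rules: Lipinski's Rule-of-Five, Oprea's ring-count/rigid-bond
boxes, and single-descriptor threshold filters such as the fractional
negatively-charged accessible surface area (FASA⁻ < 0.339). Evaluating such
rules fairly requires a reproducible pipeline: curate raw libraries, compute
a consistent descriptor panel, remove molecular-weight confounding by
resampling, score candidate filters with proper classification statistics,
and visualize chemical space. `molprofiler` implements that pipeline for
anyone comparing drug-like, non-drug-like (reagent) and natural-product
compound collections — including a seeded synthetic-library generator so the
whole analysis is runnable without access to proprietary databases.

## What it computes

* **Descriptor panel (60 descriptors)** from the hydrogen-suppressed
  molecular graph: Crippen-style additive logP, surrogate logD₇.₄ and logS,
  Ertl-style topological PSA, Lipinski and generic H-bond counts, rotatable
  bonds, composition, ring-system descriptors from an in-package SSSR
  perception (ring sizes, aromatic rings, ring assemblies, spiro atoms,
  bridged systems: assemblies in which some ring pair shares more than one
  bond), potential stereocenters/stereobonds, Kier–Hall subgraph counts
  (SC0–SC3CH), and 16 ratio descriptors built on PEOE (Gasteiger–Marsili)
  partial charges with 2D additive surface areas: FASA±/FVSA±, polar
  fractions, charge-weighted variants, f_rot, f_PSA, C3P, UNC_C3.
* **Curation**: the standard preprocessing protocol — valence check, salt and
  solvent stripping, organic-element whitelist, largest fragment,
  stereo-aware deduplication, cross-library deduplication, reactive-group
  flagging (12 SMARTS-encoded classes), MW cutoffs and MW-histogram-matched
  subset construction.
* **Filter evaluation**: confusion-matrix metrics
  SE = TP/(TP+FN), SP = TN/(TN+FP), PRE1 = TP/(TP+FP), PRE2 = TN/(TN+FN),
  GA = (TP+TN)/N and Matthews
  C = (TP·TN − FN·FP)/√((TP+FN)(TP+FP)(TN+FN)(TN+FP)),
  with an exhaustive-threshold grid search per descriptor and ranking.
* **Profiling & PCA**: per-library distribution tables, pairwise mean
  differences and KS statistics, OLS correlation, and correlation-matrix PCA
  with pooled-basis score plots.

SMILES/SDF parsing and canonicalization use RDKit; every descriptor above is
implemented in this package from the molecular graph (see
`docs/methods.md`), with all numeric tables in editable YAML config files.

## Worked example

```python
from molprofiler import (parse_smiles, compute_all, rule_of_five,
                         oprea_box, apply_threshold, FASA_MINUS_FILTER)

mol = parse_smiles("CC(=O)Oc1ccccc1C(=O)O", name="aspirin")
dv = compute_all(mol)
for k in ["MW", "AlogP", "logD7.4", "logS", "PSA", "N_rot",
          "N_HBAL", "N_HBDL", "N_Rings", "FASA-"]:
    print(f"{k:>8s}  {dv[k]:.3f}")
ro5 = rule_of_five(dv)
print("Ro5 violations:", ro5.violations, "drug-like:", ro5.druglike)
print("Oprea box:", oprea_box(dv).value)
print("FASA- < 0.339:", apply_threshold(dv, FASA_MINUS_FILTER))
```

prints

```
      MW  180.159
   AlogP  0.971
 logD7.4  -2.029
    logS  -1.237
     PSA  63.600
   N_rot  3.000
  N_HBAL  4.000
  N_HBDL  1.000
 N_Rings  1.000
   FASA-  0.431
Ro5 violations: 0 drug-like: True
Oprea box: nondruglike_box
FASA- < 0.339: False
```

Aspirin passes the Rule-of-Five with no violations (MW 180 ≤ 500, logP ≈ 1,
1 donor, 4 acceptors); its single ring and few rigid bonds put it in Oprea's
non-drug-like box, and its carboxylate-dominated surface (FASA⁻ = 0.43)
fails the FASA⁻ filter — a nice illustration that the simple filters
disagree. The logD₇.₄ sits 3 units below logP because the carboxylic acid is
treated as fully ionized at pH 7.4.

A full library run from the shell:

```bash
molprofiler simulate --class druglike   --n 1000 --seed 42 --out drug.smi
molprofiler simulate --class reagentlike --n 1000 --seed 43 --out reag.smi
molprofiler curate   --in drug.smi --out drug_cur.smi --report report.csv --mw-cutoff 600
molprofiler describe --in drug_cur.smi --out drug.csv
molprofiler describe --in reag.smi     --out reag.csv
molprofiler screen   --desc drug.csv --neg reag.csv --criterion GA --out ranking.csv
molprofiler profile  --desc drug drug.csv --desc reag reag.csv --out-dir profiles
```

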