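# Methods

This note documents the models and numerical choices behind `molprofiler`:
what each component computes, the parameters that matter, where the design
was genuinely open and what we chose, and what the synthetic benchmark does
and does not demonstrate.

## Molecular graph model

A molecule is a hydrogen-suppressed simple graph. Atoms carry element,
formal charge, attached-hydrogen count and an aromatic flag; bonds carry an
integer Kekulé order (1/2/3) *and* an aromatic flag. Storing Kekulé orders
keeps valence arithmetic exact (pyrrole N: 1+1+1H = 3) while the aromatic
flags drive aromaticity-dependent descriptors. Parsing, aromaticity
perception and canonical SMILES come from RDKit; the canonical
(stereo-aware) SMILES doubles as the structure key for deduplication.
Valence validation accepts the standard valences of C, H, O, N, P, S and the
halogens, shifted by the formal charge (N⁺ 4, O⁻ 1); elements outside that
set are passed through structurally and left to the curation whitelist.

**Ring perception** is implemented in-package. Ring bonds are the non-bridge
edges (DFS low-link). SSSR candidates are the smallest cycles through each
ring bond (BFS restricted to ring bonds); a greedy size-ordered GF(2)
independence selection over bond-incidence bitmasks yields a cycle basis of
exactly `bonds − atoms + components` rings, with a pairwise-XOR fallback for
cage graphs. *Ring assemblies* are the connected components of the ring-bond
subgraph, so fused, bridged and spiro-linked rings share an assembly. An
assembly is **bridged** iff some pair of its SSSR rings shares more than one
bond (norbornane: yes; decalin: no; spiro[4.4]nonane: no). Greedy SSSR
selection is not guaranteed minimal on arbitrary graphs, but the cardinality
is always the cyclomatic number (property-tested), and size profiles are
stable under atom relabeling on the test set.

## PEOE partial charges

Partial equalization of orbital electronegativities on the
hydrogen-expanded graph. Each atom gets an electronegativity polynomial
χ(q) = a + bq + cq² keyed by element and hybridization (classical
Gasteiger–Marsili σ parameters, shipped in `data/peoe.yaml`); in iteration k
charge Δq = (χ_high − χ_low)/χ⁺_low · 0.5ᵏ flows across each bond from the
less to the more electronegative atom, with the hydrogen cation
electronegativity fixed at 20.02. Six damped iterations (the classical
prescription) with an additional 1e-6 convergence check. Pairwise transfers
conserve total charge exactly; initial charges are the formal charges.
Hybridization is inferred from bond orders (triple or two doubles → sp;
double/aromatic → sp2; else sp3).

## Surface areas

Conformation-free 2D additive scheme (`data/radii.yaml`): each atom
contributes a sphere of its Bondi vdW radius (+1.4 Å probe for the
water-accessible variant), minus one spherical cap per bonded neighbor with
the bond length approximated by the sum of single-bond covalent radii; areas
clamp at zero, so heavily substituted atoms can be fully buried. The
absolute scale is approximate — deliberately so: everything consumed
downstream is a *fractional* surface descriptor, a ratio that is robust to
the scale. MSA (the total accessible area) is reported on this scheme's
scale and is not comparable to 3D-surface implementations.

**Fractional surface descriptors.** On the hydrogen-expanded graph, every
atom has a PEOE charge and ASA/VSA areas. FASA⁺/FASA⁻ are the area fractions
over atoms with positive/negative charge; charges with |q| < 1e-12 count to
*neither* sign, so FASA⁺ + FASA⁻ + FASA0 = 1 (FASA0 internal only — an S₈
ring has FASA⁺ = FASA⁻ = 0). FASA_P is the fraction over polar atoms
(N, O, S, P and hydrogens attached to them), FASA_H = 1 − FASA_P. FCASA± are
|q|-weighted variants; the FVSA family repeats all six on vdW areas.

## Descriptor panel

60 named descriptors per molecule. Reconstructed definitions where the
conventional name is ambiguous:

* **N_HBDL / N_HBAL** (Lipinski): hydrogens on N/O, and count of N+O atoms.
* **N_HBD / N_HBA** (generic): N/O bearing ≥1 H; acceptors exclude
  pyrrole-type nitrogens (aromatic N with three connections — the lone pair
  is in the ring) and amide nitrogens.
* **N_rot**: single non-ring bonds between two non-terminal heavy atoms,
  excluding amide C–N.
* **N_Chains / N_ChainA**: non-ring heavy atoms with / without their
  hydrogens. This is a reconstruction — the conventional table gloss is
  ambiguous — chosen so that N_Chains ≥ N_ChainA with a hydrogen-dependent
  gap.
* **N_Stereo**: saturated carbons whose four substituents (implicit H
  included) fall in four distinct graph-symmetry classes, computed by
  Morgan-style iterative neighborhood refinement. This approximates true
  stereocenter perception (no CIP rules) but is exact on typical acyclic and
  ring substitution patterns. **N_StereoB**: non-ring double bonds with two
  distinct substituents on each end.
* **N_BHA**: atoms of bridged assemblies with ≥3 incident ring bonds. The
  ring-degree rule is our fixed reading of "bridgehead atoms".
* **SC0–SC3CH** (Kier–Hall subgraph counts): closed combinatorial forms
  (Σ C(d,2), Σ C(d,3), edge-product path count minus 3·triangles); tests
  verify them against exhaustive connected-subgraph enumeration. Identities
  SC0 = N_Atom, SC1 = N_Bonds, SC3CH = N_R3 hold by construction.
* **C3P** = sp³C/(heavy − halogens); **UNC_C3** = unsaturated C/sp³C; sp³
  carbon = carbon with only single non-aromatic bonds. Zero denominators
  yield 0 plus an *undefined flag*; flagged values become NaN in tables so
  grid search and PCA can treat them explicitly (never silent NaN).

**AlogP** is a Crippen-style additive logP over ~20 compact
element/environment classes (`data/crippen_logp.yaml`); the classifier is
deliberately coarser than published 68-type schemes, and the table is
pluggable. **PSA** is an Ertl-style N/O fragment-contribution TPSA
(`data/tpsa.yaml`, published contribution values for the common
environments, explicit fallbacks otherwise). **logD₇.₄** and **logS** are
declared surrogates: logD subtracts per-group ionization penalties
(carboxylic 3.0, sulfonic 5.0, aliphatic amine 2.7 log units — groups
essentially fully ionized at pH 7.4) from AlogP; logS is a linear model
`0.8 − 0.70·AlogP − 0.0062·MW − 0.02·N_rot − 0.03·N_aromatic` chosen to
reproduce the known signs (solubility anti-correlates with MW and
lipophilicity); both coefficient sets are config files so published
regression models can be substituted.

## Curation

The seven-step protocol with these fixed choices:

* MW cutoffs use strict `<` ("lower than 600"), average atomic masses.
* Salt/solvent fragment lists are editable config; stripping applies only to
  multi-fragment records and never empties a record (if every fragment is
  listed, the largest is kept) — the compound itself may coincide with a
  listed species (acetic acid). The largest-fragment step is the safety net.
* Duplicate keys keep stereochemistry: natural products frequently differ
  only by configuration.
* The reactive filter encodes the twelve conventional reactive classes
  (aldehyde, alkyl/acyl halide, anhydride, diazo, dicarbonyl, disulfide,
  hydrazine, iso(thio)cyanate, peroxide, quaternary amine) as editable
  SMARTS; it is reported, and optionally applied.
* Therapeutic-category exclusions need external annotations; a name-list
  exclusion hook stands in.

**MW-histogram matching** (a documented reconstruction): bin both sets by MW
(default 20 Da), sample per bin without replacement in proportion to the
reference bin's relative frequency, with the scale set by the scarcest
candidate bin among bins where both sets have mass; reference-only bins
(sparse tails) are skipped rather than forcing an empty subset. Deterministic
given the seed. Finer bins trade subset size for within-bin distribution
fidelity: 20 Da bins equalize means to well under 10 Da, while a KS
statistic below 0.05 against the reference needs ~10 Da bins when candidate
and reference densities have different within-bin shapes.

## Filter evaluation

PRE1 is implemented as TP/(TP+FP) (positive predictive value) and PRE2 as
TN/(TN+FN), the evidently intended reading of the conventional metric set.
Zero-denominator metrics are NaN plus an `undefined` tag. The grid search
scans all midpoints of adjacent distinct pooled values plus one cutoff
outside each end of the range — exhaustive, hence optimal, and it dominates
any fixed-step grid; both directions are tried; ties (classification at the
cutoff) are negative (strict inequality); score ties break toward the
smaller cutoff, then below-is-positive. The default criterion is GA.
An independent O(n²) brute-force scan is kept in the tests as the oracle.

## Profiling and PCA

Sample standard deviations (ddof=1); histogram frequencies are relative
counts (sum 1); default bin widths 50 Da (MW), 0.5 (logP-family), 10 Å²
(PSA). PCA standardizes columns and eigendecomposes the correlation matrix
(descriptors span wildly different scales); constant columns are dropped,
flagged-undefined values are imputed with the fit-time column mean (0 after
standardization), and each loading vector's sign is fixed so its
largest-magnitude entry is positive, making results deterministic. Explained
fractions are eigenvalues over the number of retained columns. For
multi-library comparison the PCA is fit once on the pooled table and each
library is projected into that common basis, so score-plot panels share axes.

## Synthetic benchmark

The generator assembles molecules from weighted fragment sets
(`data/fragments.yaml`): a scaffold, then substituents at uniformly chosen
open valences until MW enters the class window; integer-seeded
`random.Random` throughout, so libraries are byte-identical across runs and
platforms. Class design targets the *qualitative* contrasts between
drug-like, reagent-like and natural-product-like collections:

* **druglike** (window 370–580 Da, mean ≈ 400): heteroaromatic scaffolds,
  amine/amide/sulfonamide/halogen substituents; nitrogen- and aromatic-rich;
  a small admixture of bridged alkaloid-like scaffolds and reactive
  substituents (~10% of molecules flag reactive, a minority, as in real
  drug-like sets). Bare halogens attach to aromatic carbons when available:
  aryl halides are the drug-like norm, alkyl halides are reactive outliers.
* **reagentlike** (240–420 Da, mean ≈ 270): small acyclic/monocyclic
  scaffolds with reactive-prone groups; few rings.
* **naturallike** (350–580 Da, mean ≈ 366): fused/bridged saturated ring
  systems (decalin-, norbornane-, adamantane-, pyranose-, sterane-like) with
  mostly hydroxyl substitution; oxygen-rich, nitrogen-free, rotatable-bond
  poor, stereocenter- and bridged-ring-rich.

Because growth stops when MW crosses the window's low edge, each class's MW
density is concentrated just above it; a *broad* library (for MW-matching
experiments) is composed as a ladder of narrow windows.

**What passing tests show — and don't.** The benchmark demonstrates that the
pipeline recovers, with correct signs, the characteristic contrasts it was
built to emulate (oxygen vs nitrogen content, aromaticity, rigidity,
bridged-ring and stereocenter content, MW ordering) and that the FASA⁻
filter behaves directionally as published (most natural-like molecules pass;
the reagent class passes least). It does not validate quantitative filter
performance on real libraries: synthetic molecules ignore synthetic
accessibility, tautomerism, charge states beyond simple rules, and the
correlation structure of real medicinal chemistry, and all absolute
surface/logP scales are this package's own.

## Problem sizes

The test suite uses a session benchmark of 2,000 molecules per class (fixed
seed), 10,000-molecule libraries for the MW-matching checks, 100 random
200+200 instances for grid-search optimality and n = 10,000 Gaussians for
PCA calibration. `scripts/acceptance.py` runs 1,000 molecules per class and
3,000 per side for MW matching; these sizes give stable means (Monte-Carlo
error well inside the asserted margins) at interactive runtimes.

## Known limitations

* 2D only: no conformers, no 3D surface areas, no force-field minimization.
* Approximate stereocenter perception (symmetry classes, not CIP).
* AlogP/PSA/logD/logS are surrogates on compact type systems; absolute
  values differ from commercial implementations even where signs and
  orderings agree.
* Greedy SSSR without guaranteed global minimality (correct cardinality
  always; exact on the tested chemistry).
* The reactive SMARTS encodings and salt/solvent lists are pragmatic,
  editable defaults, not exhaustive.
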