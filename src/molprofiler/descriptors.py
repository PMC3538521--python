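"""The 60-descriptor property panel computed from the 2D molecular graph.

44 base descriptors (hydrophobicity estimates, composition, H-bonding,
ring/chain/stereo counts and Kier–Hall subgraph counts) plus 16 ratio
descriptors (fractional rotatable bonds, fractional polar/charged surface
areas, sp3-carbon ratios).  All values are derived from the hydrogen-
suppressed graph, its PEOE charges and the 2D additive surface areas —
nothing requires 3D coordinates.

Descriptor semantics follow the field's conventional definitions where a
published definition exists (Lipinski donor/acceptor counts, Crippen-style
additive logP, Ertl-style topological PSA); logD7.4 and logS are simple
documented surrogate models with pluggable coefficients.  Values that are
undefined for a molecule (e.g. UNC_C3 with no sp3 carbon) are returned as 0
and recorded in the vector's ``flags`` set, never as silent NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .charges import hybridization, peoe_charges
from .config import load
from .molgraph import MolecularGraph, MoleculeError, RingInfo, perceive_rings, symmetry_classes
from .surfaces import AtomAnnotations, atom_surfaces

logger = logging.getLogger(__name__)

#: Standard average atomic masses (Da).
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "Si": 28.085, "B": 10.81, "Se": 78.971, "As": 74.922, "Na": 22.990,
    "K": 39.098, "Li": 6.94, "Ca": 40.078, "Mg": 24.305, "Zn": 65.38,
}

HALOGENS = frozenset(["F", "Cl", "Br", "I"])

#: The full descriptor panel, in canonical order.
BASE_DESCRIPTORS = [
    "AlogP", "logD7.4", "logS", "MW", "N_HBA", "N_HBD", "N_rot", "PSA",
    "N_HBAL", "N_HBDL", "MSA", "N_C", "N_N", "N_O", "N_Halogen", "N_Atom",
    "N_Bonds", "N_positive", "N_negative", "N_Spiro", "N_BHA", "N_Ringb",
    "N_aromatic", "N_Bridge", "N_Rings", "N_AR", "N_RA", "N_R3", "N_R4",
    "N_R5", "N_R6", "N_R7", "N_R8", "N_R9+", "N_Chains", "N_ChainA",
    "N_Stereo", "N_StereoB", "SC0", "SC1", "SC2", "SC3P", "SC3C", "SC3CH",
]
RATIO_DESCRIPTORS = [
    "f_rot", "f_PSA", "FASA+", "FASA-", "FASA_H", "FASA_P", "FCASA+",
    "FCASA-", "FVSA+", "FVSA-", "FVSA_H", "FVSA_P", "FCVSA+", "FCVSA-",
    "C3P", "UNC_C3",
]
DESCRIPTOR_NAMES = BASE_DESCRIPTORS + RATIO_DESCRIPTORS

_SIGN_EPS = 1e-12  # |q| below this counts as zero charge (neither sign)


@dataclass
class DescriptorVector:
    """Named descriptor values for one molecule, plus undefined-value flags."""
    values: dict[str, float]
    flags: set[str] = dc_field(default_factory=set)
    name: str = ""

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def is_flagged(self, key: str) -> bool:
        return key in self.flags


# -- composition --------------------------------------------------------------

def count_composition(mol: MolecularGraph) -> dict[str, float]:
    """Heavy-atom/bond counts, formal-charge counts and average-mass MW."""
    mw = 0.0
    n_c = n_n = n_o = n_hal = n_pos = n_neg = 0
    for a in mol.atoms:
        mw += ATOMIC_MASS.get(a.symbol, 0.0) + a.n_h * ATOMIC_MASS["H"]
        if a.symbol == "C":
            n_c += 1
        elif a.symbol == "N":
            n_n += 1
        elif a.symbol == "O":
            n_o += 1
        elif a.symbol in HALOGENS:
            n_hal += 1
        if a.charge > 0:
            n_pos += 1
        elif a.charge < 0:
            n_neg += 1
    return {
        "MW": mw, "N_C": n_c, "N_N": n_n, "N_O": n_o, "N_Halogen": n_hal,
        "N_Atom": mol.n_atoms, "N_Bonds": mol.n_bonds,
        "N_positive": n_pos, "N_negative": n_neg,
    }


# -- hydrogen bonding ---------------------------------------------------------

def _is_amide_n(mol: MolecularGraph, idx: int) -> bool:
    for bi in mol.adjacency()[idx]:
        b = mol.bonds[bi]
        if b.order != 1 or b.aromatic:
            continue
        c = b.other(idx)
        if mol.atoms[c].symbol != "C":
            continue
        for bj in mol.adjacency()[c]:
            b2 = mol.bonds[bj]
            if b2.order == 2 and mol.atoms[b2.other(c)].symbol in ("O", "S"):
                return True
    return False


def _is_pyrrole_type_n(mol: MolecularGraph, idx: int) -> bool:
    a = mol.atoms[idx]
    return a.aromatic and (mol.degree(idx) + a.n_h) == 3


def count_hbonds(mol: MolecularGraph) -> dict[str, int]:
    """Lipinski H-bond counts (N_HBDL = H on N/O, N_HBAL = N+O atoms) and the
    generic variants (donors = N/O bearing H; acceptors = N/O excluding
    pyrrole-type and amide nitrogens, which have no available lone pair)."""
    hbdl = hbal = hbd = hba = 0
    for i, a in enumerate(mol.atoms):
        if a.symbol not in ("N", "O"):
            continue
        hbal += 1
        hbdl += a.n_h
        if a.n_h > 0:
            hbd += 1
        if a.symbol == "O" or not (_is_pyrrole_type_n(mol, i) or _is_amide_n(mol, i)):
            hba += 1
    return {"N_HBD": hbd, "N_HBA": hba, "N_HBDL": hbdl, "N_HBAL": hbal}


# -- rotatable bonds ----------------------------------------------------------

def count_rotatable(mol: MolecularGraph) -> int:
    """Single, non-ring bonds between two non-terminal heavy atoms, excluding
    amide C–N bonds."""
    n = 0
    for b in mol.bonds:
        if b.order != 1 or b.aromatic or b.in_ring:
            continue
        if mol.degree(b.i) < 2 or mol.degree(b.j) < 2:
            continue
        if _is_amide_bond(mol, b.i, b.j):
            continue
        n += 1
    return n


def _is_amide_bond(mol: MolecularGraph, i: int, j: int) -> bool:
    for c, nn in ((i, j), (j, i)):
        if mol.atoms[c].symbol == "C" and mol.atoms[nn].symbol == "N":
            for bi in mol.adjacency()[c]:
                b = mol.bonds[bi]
                if b.order == 2 and mol.atoms[b.other(c)].symbol == "O":
                    return True
    return False


# -- ring system descriptors --------------------------------------------------

def ring_descriptors(mol: MolecularGraph, rings: RingInfo | None = None) -> dict[str, int]:
    """Ring counts from the SSSR and the ring-assembly partition.

    An assembly is *bridged* iff some pair of its SSSR rings shares more than
    one bond (norbornane yes, decalin no); N_Bridge totals the ring bonds of
    bridged assemblies and N_BHA their atoms with >= 3 incident ring bonds.
    A spiro atom is the sole common atom of some ring pair.
    """
    if rings is None:
        rings = perceive_rings(mol)
    ring_edge_sets = [rings.ring_bonds_of(r) for r in rings.sssr]
    ring_atom_sets = [set(r) for r in rings.sssr]

    n_ar = 0
    arom_bonds = {(min(b.i, b.j), max(b.i, b.j)) for b in mol.bonds if b.aromatic}
    size_counts = {k: 0 for k in range(3, 9)}
    n_r9p = 0
    for r, edges in zip(rings.sssr, ring_edge_sets):
        if edges and edges <= arom_bonds:
            n_ar += 1
        if len(r) >= 9:
            n_r9p += 1
        elif len(r) >= 3:
            size_counts[len(r)] += 1

    spiro_atoms = set()
    for a in range(len(ring_atom_sets)):
        for b in range(a + 1, len(ring_atom_sets)):
            common = ring_atom_sets[a] & ring_atom_sets[b]
            if len(common) == 1:
                spiro_atoms.update(common)

    # incident ring-bond count per atom
    ring_deg: dict[int, int] = {}
    for (i, j) in rings.ring_bond_set:
        ring_deg[i] = ring_deg.get(i, 0) + 1
        ring_deg[j] = ring_deg.get(j, 0) + 1

    n_bridge = n_bha = 0
    for asm in rings.assemblies:
        bridged = False
        for a in range(len(asm.ring_indices)):
            for b in range(a + 1, len(asm.ring_indices)):
                shared = ring_edge_sets[asm.ring_indices[a]] & ring_edge_sets[asm.ring_indices[b]]
                if len(shared) > 1:
                    bridged = True
                    break
            if bridged:
                break
        if bridged:
            n_bridge += len(asm.bonds)
            n_bha += sum(1 for at in asm.atoms if ring_deg.get(at, 0) >= 3)

    return {
        "N_Rings": rings.n_rings,
        "N_AR": n_ar,
        "N_RA": len(rings.assemblies),
        "N_R3": size_counts[3], "N_R4": size_counts[4], "N_R5": size_counts[5],
        "N_R6": size_counts[6], "N_R7": size_counts[7], "N_R8": size_counts[8],
        "N_R9+": n_r9p,
        "N_Ringb": len(rings.ring_bond_set),
        "N_aromatic": len(arom_bonds),
        "N_Spiro": len(spiro_atoms),
        "N_Bridge": n_bridge,
        "N_BHA": n_bha,
    }


# -- chains and stereocenters -------------------------------------------------

def chain_and_stereo(mol: MolecularGraph, rings: RingInfo | None = None) -> dict[str, int]:
    """Chain-atom counts and potential stereocenter/stereobond counts.

    A potential tetrahedral stereocenter is a saturated carbon whose four
    substituents (implicit H included) fall in four distinct graph-symmetry
    classes; a potential E/Z bond is a non-ring double bond with two distinct
    substituents on each end.
    """
    if rings is None:
        rings = perceive_rings(mol)
    classes = symmetry_classes(mol)

    chain_a = chains = 0
    for i, a in enumerate(mol.atoms):
        if i not in rings.ring_atom_set:
            chain_a += 1
            chains += 1 + a.n_h

    n_stereo = 0
    for i, a in enumerate(mol.atoms):
        if a.symbol != "C" or a.aromatic or a.n_h >= 2:
            continue
        if mol.degree(i) + a.n_h != 4:
            continue
        if any(mol.bonds[bi].order != 1 or mol.bonds[bi].aromatic for bi in mol.adjacency()[i]):
            continue
        nb_classes = [classes[nb] for nb in mol.neighbors(i)]
        if len(set(nb_classes)) == len(nb_classes):  # H (if any) is always distinct
            n_stereo += 1

    n_stereob = 0
    for b in mol.bonds:
        if b.order != 2 or b.aromatic or b.in_ring:
            continue
        if _end_has_distinct_subs(mol, classes, b.i, b.j) and \
           _end_has_distinct_subs(mol, classes, b.j, b.i):
            n_stereob += 1

    return {"N_Chains": chains, "N_ChainA": chain_a,
            "N_Stereo": n_stereo, "N_StereoB": n_stereob}


def _end_has_distinct_subs(mol: MolecularGraph, classes: list[int], end: int, partner: int) -> bool:
    a = mol.atoms[end]
    if a.n_h >= 2:
        return False
    heavy = [classes[nb] for nb in mol.neighbors(end) if nb != partner]
    if len(heavy) + a.n_h != 2:
        return False
    if a.n_h == 1:
        return True  # one heavy substituent + H, always distinct
    return heavy[0] != heavy[1]


# -- Kier & Hall subgraph counts ----------------------------------------------

def subgraph_counts(mol: MolecularGraph) -> dict[str, int]:
    """Connected-subgraph counts of the heavy-atom graph.

    SC0/SC1 are atom/bond counts; SC2 counts 2-edge paths; SC3P 3-edge paths,
    SC3C 3-edge stars (K_{1,3}) and SC3CH 3-edge rings (triangles).  Closed
    combinatorial forms are used; tests validate them against brute-force
    subgraph enumeration.
    """
    deg = [mol.degree(i) for i in range(mol.n_atoms)]
    sc2 = sum(d * (d - 1) // 2 for d in deg)
    sc3c = sum(d * (d - 1) * (d - 2) // 6 for d in deg)
    nbr_sets = [set(mol.neighbors(i)) for i in range(mol.n_atoms)]
    triangles = 0
    for b in mol.bonds:
        triangles += len(nbr_sets[b.i] & nbr_sets[b.j])
    triangles //= 3
    sc3p = sum((deg[b.i] - 1) * (deg[b.j] - 1) for b in mol.bonds) - 3 * triangles
    return {"SC0": mol.n_atoms, "SC1": mol.n_bonds, "SC2": sc2,
            "SC3P": sc3p, "SC3C": sc3c, "SC3CH": triangles}


# -- hydrophobicity: Crippen-style additive logP ------------------------------

def _crippen_type(mol: MolecularGraph, idx: int) -> str:
    a = mol.atoms[idx]
    nbrs = [mol.atoms[n].symbol for n in mol.neighbors(idx)]
    if a.symbol == "C":
        het = any(s not in ("C", "H") for s in nbrs)
        if a.aromatic:
            return "C.ar.het" if het else "C.ar"
        hyb = hybridization(mol, idx)
        if hyb == "sp":
            return "C.sp"
        if hyb == "sp2":
            for bi in mol.adjacency()[idx]:
                b = mol.bonds[bi]
                if b.order == 2 and mol.atoms[b.other(idx)].symbol in ("O", "S"):
                    return "C.sp2.carbonyl"
            return "C.sp2"
        return "C.sp3.het" if het else "C.sp3"
    if a.symbol == "O":
        if a.charge < 0:
            return "O.minus"
        if a.aromatic:
            return "O.ar"
        if any(mol.bonds[bi].order == 2 for bi in mol.adjacency()[idx]):
            return "O.carbonyl"
        return "O.OH" if a.n_h else "O.ether"
    if a.symbol == "N":
        if a.charge > 0:
            return "N.plus"
        if a.aromatic:
            return "N.ar"
        if _is_amide_n(mol, idx):
            return "N.amide"
        if hybridization(mol, idx) != "sp3":
            return "N.sp2"
        return "N.sp3"
    if a.symbol in ("S", "P", "F", "Cl", "Br", "I"):
        return a.symbol
    return "wildcard"


def compute_logp(mol: MolecularGraph) -> float:
    """Additive atomic-contribution logP (Crippen-style, shipped table)."""
    table = load("crippen_logp")["contributions"]
    total = 0.0
    for i, a in enumerate(mol.atoms):
        t = _crippen_type(mol, i)
        if t == "wildcard":
            logger.debug("logP wildcard atom type: %s in %s", a.symbol, mol.smiles or mol.name)
        total += table.get(t, table["wildcard"])
        h_type = "H.het" if a.symbol in ("N", "O", "S", "P") else "H.C"
        total += a.n_h * table[h_type]
    return total


# -- polar surface area -------------------------------------------------------

def _tpsa_type(mol: MolecularGraph, idx: int) -> str:
    a = mol.atoms[idx]
    adj = mol.adjacency()[idx]
    orders = [mol.bonds[bi].order for bi in adj]
    if a.symbol == "N":
        if a.charge > 0:
            if a.aromatic:
                return "n.arH+" if a.n_h else "n.ar+"
            return {3: "NH3+", 2: "NH2+", 1: "NH+"}.get(a.n_h, "N4+")
        if a.aromatic:
            if a.n_h:
                return "n.arH"
            return "n.ar3" if len(adj) + a.n_h == 3 else "n.ar"
        if 3 in orders:
            return "N1#"
        if 2 in orders:
            if a.n_h and len(adj) == 1:
                return "NH="
            return "N3=" if len(adj) + a.n_h == 3 else "N2="
        return {0: "N3", 1: "NH"}.get(a.n_h, "NH2")
    if a.symbol == "O":
        if a.charge < 0:
            return "O-"
        if a.aromatic:
            return "o.ar"
        if 2 in orders:
            return "O="
        return "OH" if a.n_h else "O2"
    raise ValueError(f"no TPSA type for element {a.symbol}")


def compute_tpsa(mol: MolecularGraph) -> float:
    """Ertl-style fragment-contribution topological PSA over N/O atoms."""
    table = load("tpsa")["contributions"]
    total = 0.0
    for i, a in enumerate(mol.atoms):
        if a.symbol not in ("N", "O"):
            continue
        t = _tpsa_type(mol, i)
        fallback = "N.fallback" if a.symbol == "N" else "O.fallback"
        total += table.get(t, table[fallback])
    return total


# -- logD7.4 / logS surrogates ------------------------------------------------

def _ionizable_groups(mol: MolecularGraph) -> dict[str, int]:
    """Counts of groups treated as ionized at pH 7.4."""
    counts = {"carboxylic_acid": 0, "sulfonic_acid": 0, "aliphatic_amine": 0}
    for i, a in enumerate(mol.atoms):
        if a.symbol == "C":
            has_dbl_o = has_oh = False
            for bi in mol.adjacency()[i]:
                b = mol.bonds[bi]
                o = b.other(i)
                if mol.atoms[o].symbol != "O":
                    continue
                if b.order == 2:
                    has_dbl_o = True
                elif b.order == 1 and (mol.atoms[o].n_h > 0 or mol.atoms[o].charge < 0):
                    has_oh = True
            if has_dbl_o and has_oh:
                counts["carboxylic_acid"] += 1
        elif a.symbol == "S":
            dbl_o = sum(
                1 for bi in mol.adjacency()[i]
                if mol.bonds[bi].order == 2 and mol.atoms[mol.bonds[bi].other(i)].symbol == "O"
            )
            oh = any(
                mol.bonds[bi].order == 1
                and mol.atoms[mol.bonds[bi].other(i)].symbol == "O"
                and (mol.atoms[mol.bonds[bi].other(i)].n_h > 0
                     or mol.atoms[mol.bonds[bi].other(i)].charge < 0)
                for bi in mol.adjacency()[i]
            )
            if dbl_o >= 2 and oh:
                counts["sulfonic_acid"] += 1
        elif a.symbol == "N":
            if a.aromatic or a.charge != 0:
                continue
            if any(mol.bonds[bi].order != 1 or mol.bonds[bi].aromatic
                   for bi in mol.adjacency()[i]):
                continue
            if _is_amide_n(mol, i):
                continue
            counts["aliphatic_amine"] += 1
    return counts


def compute_logd_logs(
    mol: MolecularGraph, alogp: float | None = None, counts: dict | None = None
) -> dict[str, float]:
    """Surrogate logD7.4 (AlogP minus per-group ionization penalties) and
    surrogate logS (linear model on AlogP, MW, N_rot and aromatic bonds)."""
    cfg = load("logd_logs")
    if alogp is None:
        alogp = compute_logp(mol)
    if counts is None:
        counts = count_composition(mol)
    penalties = cfg["logd_penalties"]
    groups = _ionizable_groups(mol)
    logd = alogp - sum(penalties[g] * n for g, n in groups.items())
    c = cfg["logs_coefficients"]
    n_aromatic = sum(1 for b in mol.bonds if b.aromatic)
    logs = (c["intercept"] + c["alogp"] * alogp + c["mw"] * counts["MW"]
            + c["n_rot"] * count_rotatable(mol) + c["n_aromatic"] * n_aromatic)
    return {"logD7.4": logd, "logS": logs}


# -- fractional surface descriptors -------------------------------------------

def surface_descriptors(
    mol: MolecularGraph,
    expanded: MolecularGraph | None = None,
    ann: AtomAnnotations | None = None,
) -> tuple[dict[str, float], set[str]]:
    """MSA and the twelve fractional surface-area descriptors.

    Works on the hydrogen-expanded graph: every atom (H included) carries a
    PEOE charge and ASA/VSA areas.  FASA+/FASA- are area fractions over
    positively/negatively charged atoms (zero charge counts to neither sign,
    so FASA+ + FASA- + FASA0 = 1); FASA_P is the polar fraction (N, O, S, P
    and hydrogens attached to them); FCASA± are |q|-weighted variants. The
    FVSA family repeats the six with van der Waals areas.
    """
    if expanded is None:
        expanded, _ = mol.with_explicit_hydrogens()
    if ann is None:
        ann = atom_surfaces(expanded)
        ann.peoe_charge = peoe_charges(expanded)
    q = ann.peoe_charge
    flags: set[str] = set()

    polar = np.zeros(expanded.n_atoms, dtype=bool)
    for i, a in enumerate(expanded.atoms):
        if a.symbol in ("N", "O", "S", "P"):
            polar[i] = True
        elif a.symbol == "H":
            nbrs = expanded.neighbors(i)
            if nbrs and expanded.atoms[nbrs[0]].symbol in ("N", "O", "S", "P"):
                polar[i] = True

    pos = q > _SIGN_EPS
    neg = q < -_SIGN_EPS
    out: dict[str, float] = {}
    for fam, area in (("ASA", ann.asa), ("VSA", ann.vsa)):
        total = float(area.sum())
        if total <= 0.0:
            raise MoleculeError(f"zero total {fam} — surface descriptors undefined")
        out[f"F{fam}+"] = float(area[pos].sum()) / total
        out[f"F{fam}-"] = float(area[neg].sum()) / total
        out[f"F{fam}_P"] = float(area[polar].sum()) / total
        out[f"F{fam}_H"] = 1.0 - out[f"F{fam}_P"]
        wtotal = float((np.abs(q) * area).sum())
        if wtotal <= 0.0:
            out[f"FC{fam}+"] = 0.0
            out[f"FC{fam}-"] = 0.0
            flags.update((f"FC{fam}+", f"FC{fam}-"))
        else:
            out[f"FC{fam}+"] = float((np.abs(q) * area)[pos].sum()) / wtotal
            out[f"FC{fam}-"] = float((np.abs(q) * area)[neg].sum()) / wtotal
    out["MSA"] = float(ann.asa.sum())
    return out, flags


# -- simple ratios ------------------------------------------------------------

def _sp3_unsat_carbons(mol: MolecularGraph) -> tuple[int, int]:
    sp3 = unsat = 0
    for i, a in enumerate(mol.atoms):
        if a.symbol != "C":
            continue
        if a.aromatic or any(mol.bonds[bi].order > 1 for bi in mol.adjacency()[i]):
            unsat += 1
        else:
            sp3 += 1
    return sp3, unsat


def ratio_descriptors(mol: MolecularGraph, dv: dict[str, float]) -> tuple[dict[str, float], set[str]]:
    """f_rot, f_PSA and the sp3-carbon ratios C3P / UNC_C3.

    C3P = sp3 C / (heavy atoms − halogens); UNC_C3 = unsaturated C / sp3 C.
    Zero denominators yield 0 with the descriptor name flagged.
    """
    flags: set[str] = set()
    out: dict[str, float] = {}
    if dv["N_Bonds"] > 0:
        out["f_rot"] = dv["N_rot"] / dv["N_Bonds"]
    else:
        out["f_rot"] = 0.0
        flags.add("f_rot")
    out["f_PSA"] = dv["PSA"] / dv["MSA"] if dv["MSA"] > 0 else 0.0
    sp3, unsat = _sp3_unsat_carbons(mol)
    denom = dv["N_Atom"] - dv["N_Halogen"]
    if denom > 0:
        out["C3P"] = sp3 / denom
    else:
        out["C3P"] = 0.0
        flags.add("C3P")
    if sp3 > 0:
        out["UNC_C3"] = unsat / sp3
    else:
        out["UNC_C3"] = 0.0
        flags.add("UNC_C3")
    return out, flags


# -- the full panel -----------------------------------------------------------

def compute_all(mol: MolecularGraph) -> DescriptorVector:
    """Compute the full 60-descriptor vector for one single-fragment molecule."""
    if len(mol.components()) != 1:
        raise MoleculeError(
            "descriptor panel requires a single-fragment molecule "
            "(run curation first)", mol.smiles,
        )
    values: dict[str, float] = {}
    flags: set[str] = set()

    values.update(count_composition(mol))
    values.update(count_hbonds(mol))
    values["N_rot"] = count_rotatable(mol)
    rings = perceive_rings(mol)
    values.update(ring_descriptors(mol, rings))
    values.update(chain_and_stereo(mol, rings))
    values.update(subgraph_counts(mol))
    values["AlogP"] = compute_logp(mol)
    values["PSA"] = compute_tpsa(mol)
    values.update(compute_logd_logs(mol, alogp=values["AlogP"], counts=values))

    expanded, _ = mol.with_explicit_hydrogens()
    ann = atom_surfaces(expanded)
    ann.peoe_charge = peoe_charges(expanded)
    surf, sflags = surface_descriptors(mol, expanded, ann)
    values.update(surf)
    flags |= sflags

    ratios, rflags = ratio_descriptors(mol, values)
    values.update(ratios)
    flags |= rflags

    ordered = {k: float(values[k]) for k in DESCRIPTOR_NAMES}
    return DescriptorVector(ordered, flags, name=mol.name or mol.smiles)


def compute_table(mols: list[MolecularGraph]) -> pd.DataFrame:
    """Descriptor DataFrame for a library: one row per molecule, columns in
    panel order plus a ``flags`` column; flagged-undefined cells are NaN."""
    rows = []
    flag_col = []
    names = []
    for m in mols:
        dv = compute_all(m)
        row = dict(dv.values)
        for f in dv.flags:
            row[f] = np.nan
        rows.append(row)
        flag_col.append(";".join(sorted(dv.flags)))
        names.append(dv.name)
    df = pd.DataFrame(rows, columns=DESCRIPTOR_NAMES)
    df.insert(0, "name", names)
    df["flags"] = flag_col
    return df
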