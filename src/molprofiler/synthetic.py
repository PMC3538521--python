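"""Seeded generator of synthetic compound classes.

Because the real screening libraries behind drug-likeness studies are
proprietary, the pipeline is exercised on synthetic classes built by a
fragment-assembly generator: a weighted scaffold is drawn, then weighted
substituents are attached at uniformly chosen open valences until the
molecular weight enters the class window.  The three built-in classes
(druglike, reagentlike, naturallike) are calibrated qualitatively — sign and
ordering of the characteristic property contrasts (oxygen vs nitrogen
content, aromaticity, rigidity, bridged-ring content, stereocenter count,
molecular weight) — not to quantitative means of any real library.

Everything is driven by ``random.Random`` with integer-derived seeds, so a
fixed seed reproduces a library byte-identically across platforms.
"""

from __future__ import annotations

import functools
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors

from .config import load
from .molgraph import MolecularGraph, from_rdkit

CLASSES = ("druglike", "reagentlike", "naturallike")

_MAX_ATTEMPTS = 60
_H_MASS = 1.008


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one synthetic compound class."""
    mol_class: str
    n: int
    rng_seed: int
    mw_window: tuple[float, float] | None = None
    fragment_weights: dict | None = None

    def __post_init__(self):
        if self.mol_class not in CLASSES:
            raise ValueError(f"unknown class {self.mol_class!r}")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.mw_window is not None and not self.mw_window[0] < self.mw_window[1]:
            raise ValueError("mw_window must satisfy low < high")


@functools.lru_cache(maxsize=None)
def _class_config(mol_class: str):
    cfg = load("fragments")["classes"][mol_class]
    scaffolds = []
    for smi, w in cfg["scaffolds"].items():
        rd = Chem.MolFromSmiles(smi)
        if rd is None:
            raise ValueError(f"bad scaffold SMILES in config: {smi!r}")
        scaffolds.append((rd, RDDescriptors.MolWt(rd), float(w)))
    subs = []
    for smi, w in cfg["substituents"].items():
        rd = Chem.MolFromSmiles(smi)
        if rd is None:
            raise ValueError(f"bad substituent SMILES in config: {smi!r}")
        if rd.GetAtomWithIdx(0).GetTotalNumHs() < 1:
            raise ValueError(f"substituent attachment atom has no open valence: {smi!r}")
        subs.append((rd, RDDescriptors.MolWt(rd), float(w)))
    window = tuple(cfg["mw_window"])
    return scaffolds, subs, window


def _weighted_choice(rng: random.Random, items: list, weights: list[float]):
    total = sum(weights)
    x = rng.random() * total
    acc = 0.0
    for item, w in zip(items, weights):
        acc += w
        if x < acc:
            return item
    return items[-1]


def _open_sites(rd: Chem.Mol, carbon_only: bool, aromatic_preferred: bool = False) -> list[int]:
    sites = []
    aromatic_sites = []
    for atom in rd.GetAtoms():
        if atom.GetTotalNumHs() < 1 or atom.GetFormalCharge() != 0:
            continue
        sym = atom.GetSymbol()
        if sym == "C" or (sym == "N" and not carbon_only):
            sites.append(atom.GetIdx())
            if sym == "C" and atom.GetIsAromatic():
                aromatic_sites.append(atom.GetIdx())
    if aromatic_preferred and aromatic_sites:
        return aromatic_sites
    return sites


def _attach(rd: Chem.Mol, site: int, frag: Chem.Mol) -> Chem.Mol:
    combo = Chem.RWMol(Chem.CombineMols(rd, frag))
    combo.AddBond(site, rd.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def sample_molecule(spec: LibrarySpec, rng: random.Random) -> MolecularGraph:
    """Grow one molecule of the spec's class until its MW enters the window.

    Deterministic for a given RNG state; raises after a bounded number of
    failed growth attempts (which only happens with pathological windows).
    """
    scaffolds, subs, default_window = _class_config(spec.mol_class)
    low, high = spec.mw_window or default_window

    for _ in range(_MAX_ATTEMPTS):
        rd, mw, _ = _weighted_choice(rng, scaffolds, [s[2] for s in scaffolds])
        rd = Chem.Mol(rd)
        stuck = 0
        while mw < low and stuck < 10:
            frag, frag_mw, _ = _weighted_choice(rng, subs, [s[2] for s in subs])
            if mw + frag_mw - 2 * _H_MASS > high:
                stuck += 1
                continue
            # heteroatom-attaching substituents only bond to carbon sites;
            # bare halogens go to aromatic carbons when present (aryl
            # halides are the norm in drug-like chemistry, alkyl halides
            # are reactive outliers)
            attach_sym = frag.GetAtomWithIdx(0).GetSymbol()
            carbon_only = attach_sym != "C"
            halogen = frag.GetNumAtoms() == 1 and attach_sym in ("F", "Cl", "Br", "I")
            sites = _open_sites(rd, carbon_only, aromatic_preferred=halogen)
            if not sites:
                break
            site = sites[rng.randrange(len(sites))]
            try:
                rd = _attach(rd, site, frag)
            except Exception:
                stuck += 1
                continue
            mw += frag_mw - 2 * _H_MASS
        if low <= mw <= high:
            return from_rdkit(rd)
    raise RuntimeError(
        f"could not reach MW window {low}-{high} for class {spec.mol_class!r}")


def sample_library(spec: LibrarySpec) -> list[MolecularGraph]:
    """Generate ``spec.n`` molecules named ``<class>_<index>``."""
    rng = random.Random(spec.rng_seed)
    out = []
    for k in range(spec.n):
        mol = sample_molecule(spec, rng)
        mol.name = f"{spec.mol_class}_{k:05d}"
        out.append(mol)
    return out


@dataclass
class Benchmark:
    libraries: dict[str, list[MolecularGraph]]
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_labeled_benchmark(
    n_per_class: int, seed: int, out_dir: str | Path | None = None
) -> Benchmark:
    """Three class libraries of equal size plus a (name, class) label table.

    Per-class seeds are derived from ``seed`` so the classes are independent
    streams; with ``out_dir`` set, one SMILES file per class and a labels CSV
    are written (byte-identical for a fixed seed).
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    libraries = {}
    rows = []
    for k, cls in enumerate(CLASSES):
        spec = LibrarySpec(cls, n_per_class, rng_seed=(seed * 1000003 + k) % (2**31))
        libraries[cls] = sample_library(spec)
        rows.extend({"name": m.name, "class": cls} for m in libraries[cls])
    labels = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cls, mols in libraries.items():
            with open(out_dir / f"{cls}.smi", "w") as fh:
                for m in mols:
                    fh.write(f"{m.smiles}\t{m.name}\n")
        labels.to_csv(out_dir / "labels.csv", index=False)
    return Benchmark(libraries=libraries, labels=labels)
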