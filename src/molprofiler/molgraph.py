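"""Molecular data model, file I/O and ring perception.

The package represents a molecule as a plain hydrogen-suppressed graph
(:class:`MolecularGraph`): atoms carry element, formal charge, attached-H
count and an aromatic flag; bonds carry an integer (Kekulé) order plus an
aromatic flag.  SMILES/SDF reading and canonicalization are delegated to
RDKit; everything downstream (ring analysis, charges, surface areas and the
descriptor panel) works on this graph only.

Ring perception is implemented here directly: a smallest-set-of-smallest-rings
(SSSR) cycle basis of cardinality ``bonds - atoms + components``, plus a
partition of the ring bonds into *ring assemblies* (fused/bridged/spiro
connected components), which the ring descriptors consume.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements with tabulated valences; others are accepted structurally but
#: cannot be validated (curation removes them anyway).
_ALLOWED_VALENCES = {
    "H": {1},
    "C": {4},
    "N": {3},
    "O": {2},
    "P": {3, 5},
    "S": {2, 4, 6},
    "F": {1},
    "Cl": {1},
    "Br": {1},
    "I": {1},
}

ORGANIC_ELEMENTS = frozenset(["C", "H", "O", "N", "P", "S", "F", "Cl", "Br", "I"])


class MoleculeError(ValueError):
    """Raised for unparseable or valence-violating structures.

    Carries the offending input text in ``.input_text``.
    """

    def __init__(self, message: str, input_text: str = ""):
        super().__init__(message)
        self.input_text = input_text


@dataclass(frozen=True)
class Atom:
    symbol: str
    charge: int = 0
    n_h: int = 0
    aromatic: bool = False
    in_ring: bool = False


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int = 1          # Kekulé order 1/2/3
    aromatic: bool = False
    in_ring: bool = False

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class MolecularGraph:
    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    smiles: str = ""        # canonical SMILES when built from RDKit

    _adj: list[list[int]] | None = field(default=None, repr=False, compare=False)

    # -- basic graph accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def adjacency(self) -> list[list[int]]:
        """Bond indices incident to each atom (cached)."""
        if self._adj is None:
            adj: list[list[int]] = [[] for _ in self.atoms]
            for bi, b in enumerate(self.bonds):
                adj[b.i].append(bi)
                adj[b.j].append(bi)
            self._adj = adj
        return self._adj

    def neighbors(self, idx: int) -> list[int]:
        return [self.bonds[bi].other(idx) for bi in self.adjacency()[idx]]

    def degree(self, idx: int) -> int:
        return len(self.adjacency()[idx])

    def components(self) -> list[list[int]]:
        """Connected components as sorted atom-index lists."""
        seen = [False] * self.n_atoms
        out = []
        for start in range(self.n_atoms):
            if seen[start]:
                continue
            comp = []
            stack = [start]
            seen[start] = True
            while stack:
                a = stack.pop()
                comp.append(a)
                for nb in self.neighbors(a):
                    if not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            out.append(sorted(comp))
        return out

    def permute(self, perm: Sequence[int]) -> "MolecularGraph":
        """Relabel atoms: atom ``i`` becomes atom ``perm[i]``."""
        new_atoms: list[Atom | None] = [None] * self.n_atoms
        for i, a in enumerate(self.atoms):
            new_atoms[perm[i]] = a
        new_bonds = [
            Bond(min(perm[b.i], perm[b.j]), max(perm[b.i], perm[b.j]),
                 b.order, b.aromatic, b.in_ring)
            for b in self.bonds
        ]
        return MolecularGraph(list(new_atoms), new_bonds, self.name, self.smiles)

    def with_explicit_hydrogens(self) -> tuple["MolecularGraph", list[int]]:
        """Expand implicit hydrogens to explicit H atoms.

        Returns the expanded graph and, for each expanded atom, the index of
        the heavy atom it belongs to (heavy atoms map to themselves).
        """
        atoms = []
        parents = []
        bonds = list(self.bonds)
        for i, a in enumerate(self.atoms):
            atoms.append(Atom(a.symbol, a.charge, 0, a.aromatic, a.in_ring))
            parents.append(i)
        for i, a in enumerate(self.atoms):
            for _ in range(a.n_h):
                h_idx = len(atoms)
                atoms.append(Atom("H"))
                parents.append(i)
                bonds.append(Bond(i, h_idx, 1, False, False))
        return MolecularGraph(atoms, bonds, self.name, self.smiles), parents


# -- RDKit bridge -------------------------------------------------------------

def from_rdkit(rdmol: Chem.Mol, name: str = "") -> MolecularGraph:
    """Convert a sanitized RDKit molecule into a :class:`MolecularGraph`."""
    kek = Chem.Mol(rdmol)
    Chem.Kekulize(kek, clearAromaticFlags=False)
    atoms = [
        Atom(
            symbol=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = []
    for b in kek.GetBonds():
        order = int(round(b.GetBondTypeAsDouble()))
        bonds.append(
            Bond(
                min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                order=max(order, 1),
                aromatic=rdmol.GetBondWithIdx(b.GetIdx()).GetIsAromatic(),
            )
        )
    mol = MolecularGraph(atoms, bonds, name=name, smiles=Chem.MolToSmiles(rdmol))
    _assign_ring_flags(mol)
    return mol


def to_rdkit(mol: MolecularGraph) -> Chem.Mol:
    """Rebuild an RDKit molecule (used for SMARTS matching and writing)."""
    if mol.smiles:
        rd = Chem.MolFromSmiles(mol.smiles)
        if rd is not None:
            return rd
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.symbol)
        ra.SetFormalCharge(a.charge)
        ra.SetNumExplicitHs(a.n_h)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, order_map[b.order])
    rd = rw.GetMol()
    Chem.SanitizeMol(rd)
    return rd


def parse_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Parse one SMILES record (multi-fragment inputs stay multi-component)."""
    if not smiles or not smiles.strip():
        raise MoleculeError("empty SMILES", smiles)
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise MoleculeError(f"cannot parse SMILES: {smiles!r}", smiles)
    return from_rdkit(rd, name=name)


def write_smiles(mol: MolecularGraph) -> str:
    if mol.smiles:
        return mol.smiles
    return Chem.MolToSmiles(to_rdkit(mol))


@dataclass(frozen=True)
class Rejection:
    record_index: int
    input_text: str
    reason: str


def read_library(
    path: str | Path, format: str | None = None
) -> tuple[list[MolecularGraph], list[Rejection]]:
    """Read a compound library; bad records are logged, never fatal.

    ``format`` is ``"smiles"`` (one record per line, optional name column,
    ``#`` comments) or ``"sdf"`` (V2000); inferred from the suffix if omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smiles"
    mols: list[MolecularGraph] = []
    rejections: list[Rejection] = []
    if format == "smiles":
        with open(path) as fh:
            for idx, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smi = parts[0]
                name = parts[1].strip() if len(parts) > 1 else ""
                try:
                    mols.append(parse_smiles(smi, name=name))
                except MoleculeError as exc:
                    rejections.append(Rejection(idx, line, str(exc)))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for idx, rd in enumerate(supplier):
            if rd is None:
                rejections.append(Rejection(idx, f"<SDF record {idx}>", "unparseable SDF record"))
                continue
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
            mols.append(from_rdkit(rd, name=name))
    else:
        raise ValueError(f"unknown format: {format!r}")
    return mols, rejections


# -- valence validation -------------------------------------------------------

def check_valences(mol: MolecularGraph) -> bool:
    """True if every atom with a tabulated element has an allowed valence.

    The valence is the Kekulé bond-order sum plus attached hydrogens; a
    positive formal charge raises the allowed valences by the charge and a
    negative charge lowers them (e.g. N+ 4, O- 1).
    """
    order_sum = [0] * mol.n_atoms
    for b in mol.bonds:
        order_sum[b.i] += b.order
        order_sum[b.j] += b.order
    for i, a in enumerate(mol.atoms):
        base = _ALLOWED_VALENCES.get(a.symbol)
        if base is None:
            continue
        allowed = {max(v + a.charge, 0) for v in base}
        if order_sum[i] + a.n_h not in allowed:
            return False
    return True


# -- ring perception ----------------------------------------------------------

@dataclass
class RingAssembly:
    atoms: frozenset[int]
    bonds: frozenset[tuple[int, int]]
    ring_indices: tuple[int, ...]


@dataclass
class RingInfo:
    sssr: list[list[int]]                    # ordered atom cycles
    ring_bond_set: frozenset[tuple[int, int]]
    ring_atom_set: frozenset[int]
    assemblies: list[RingAssembly]

    @property
    def n_rings(self) -> int:
        return len(self.sssr)

    def ring_bonds_of(self, ring: Sequence[int]) -> frozenset[tuple[int, int]]:
        n = len(ring)
        return frozenset(
            (min(ring[k], ring[(k + 1) % n]), max(ring[k], ring[(k + 1) % n]))
            for k in range(n)
        )


def _ring_bonds(mol: MolecularGraph) -> set[tuple[int, int]]:
    """Bonds in at least one cycle = non-bridge edges (DFS low-link)."""
    adj = mol.adjacency()
    n = mol.n_atoms
    disc = [-1] * n
    low = [0] * n
    bridges: set[int] = set()
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        stack: list[tuple[int, int, int]] = [(root, -1, 0)]  # atom, parent bond, edge ptr
        while stack:
            v, pb, ptr = stack.pop()
            if ptr == 0:
                disc[v] = low[v] = timer
                timer += 1
            if ptr < len(adj[v]):
                stack.append((v, pb, ptr + 1))
                bi = adj[v][ptr]
                if bi == pb:
                    continue
                w = mol.bonds[bi].other(v)
                if disc[w] == -1:
                    stack.append((w, bi, 0))
                else:
                    low[v] = min(low[v], disc[w])
            else:
                if pb != -1:
                    p = mol.bonds[pb].other(v)
                    low[p] = min(low[p], low[v])
                    if low[v] > disc[p]:
                        bridges.add(pb)
    out = set()
    # multi-edges cannot occur (simple graph); every non-bridge edge in a
    # connected component with a cycle is a ring bond
    for bi, b in enumerate(mol.bonds):
        if bi not in bridges:
            out.add((b.i, b.j))
    return out


def _assign_ring_flags(mol: MolecularGraph) -> None:
    rb = _ring_bonds(mol)
    ring_atoms = {i for pair in rb for i in pair}
    mol.bonds = [
        Bond(b.i, b.j, b.order, b.aromatic, (b.i, b.j) in rb) for b in mol.bonds
    ]
    mol.atoms = [
        Atom(a.symbol, a.charge, a.n_h, a.aromatic, i in ring_atoms)
        for i, a in enumerate(mol.atoms)
    ]
    mol._adj = None


def _shortest_cycle_through(
    mol: MolecularGraph, bond: Bond, ring_bonds: set[tuple[int, int]]
) -> list[int] | None:
    """Smallest cycle containing ``bond``: BFS shortest path avoiding the bond,
    restricted to ring bonds."""
    src, dst = bond.i, bond.j
    prev: dict[int, int] = {src: -1}
    q = deque([src])
    while q:
        v = q.popleft()
        if v == dst:
            break
        for bi in mol.adjacency()[v]:
            b = mol.bonds[bi]
            key = (b.i, b.j)
            if key not in ring_bonds or (b.i == bond.i and b.j == bond.j):
                continue
            w = b.other(v)
            if w not in prev:
                prev[w] = v
                q.append(w)
    if dst not in prev:
        return None
    path = [dst]
    while path[-1] != src:
        path.append(prev[path[-1]])
    return path  # ordered cycle (closing bond = the excluded bond)


def perceive_rings(mol: MolecularGraph) -> RingInfo:
    """SSSR cycle basis plus ring-assembly partition.

    The basis has cardinality ``bonds - atoms + components`` (cyclomatic
    number).  Candidate rings are the smallest cycles through each ring bond;
    a greedy size-ordered GF(2) independence selection yields the basis.
    Assemblies are the connected components of the ring-bond subgraph, so
    fused, bridged and spiro-linked rings share one assembly.
    """
    ring_bonds = _ring_bonds(mol)
    n_expected = mol.n_bonds - mol.n_atoms + len(mol.components())
    bond_index = {(b.i, b.j): k for k, b in enumerate(mol.bonds)}

    candidates: list[list[int]] = []
    seen_sets: set[frozenset[tuple[int, int]]] = set()
    for b in mol.bonds:
        if (b.i, b.j) not in ring_bonds:
            continue
        cyc = _shortest_cycle_through(mol, b, ring_bonds)
        if cyc is None:
            continue
        edges = frozenset(
            (min(cyc[k], cyc[(k + 1) % len(cyc)]), max(cyc[k], cyc[(k + 1) % len(cyc)]))
            for k in range(len(cyc))
        )
        if edges not in seen_sets:
            seen_sets.add(edges)
            candidates.append(cyc)

    candidates.sort(key=lambda c: (len(c), sorted(bond_index[e] for e in _cycle_edges(c))))

    sssr: list[list[int]] = []
    basis: list[int] = []  # bitmasks over bond indices
    for cyc in candidates:
        if len(sssr) == n_expected:
            break
        vec = 0
        for e in _cycle_edges(cyc):
            vec |= 1 << bond_index[e]
        red = vec
        for bv in basis:
            red = min(red, red ^ bv)
        if red:
            basis.append(vec)
            sssr.append(cyc)

    # fallback: if greedy candidates were insufficient (rare cage graphs),
    # extend with XOR combinations — molecule-scale graphs never hit this in
    # practice, but the cyclomatic invariant must hold
    if len(sssr) < n_expected:
        for cyc_a, cyc_b in itertools.combinations(candidates, 2):
            va = 0
            for e in _cycle_edges(cyc_a):
                va |= 1 << bond_index[e]
            vb = 0
            for e in _cycle_edges(cyc_b):
                vb |= 1 << bond_index[e]
            vec = va ^ vb
            ordered = _order_edge_set(mol, vec)
            if ordered is None:
                continue
            red = vec
            for bv in basis:
                red = min(red, red ^ bv)
            if red:
                basis.append(vec)
                sssr.append(ordered)
                if len(sssr) == n_expected:
                    break

    ring_atom_set = frozenset(i for pair in ring_bonds for i in pair)
    assemblies = _build_assemblies(mol, sssr, ring_bonds)
    return RingInfo(
        sssr=sssr,
        ring_bond_set=frozenset(ring_bonds),
        ring_atom_set=ring_atom_set,
        assemblies=assemblies,
    )


def _cycle_edges(cyc: Sequence[int]) -> list[tuple[int, int]]:
    n = len(cyc)
    return [(min(cyc[k], cyc[(k + 1) % n]), max(cyc[k], cyc[(k + 1) % n])) for k in range(n)]


def _order_edge_set(mol: MolecularGraph, vec: int) -> list[int] | None:
    """Order a GF(2) edge set into a simple cycle, or None if it is not one."""
    edges = [mol.bonds[k] for k in range(mol.n_bonds) if vec >> k & 1]
    if not edges:
        return None
    adj: dict[int, list[int]] = {}
    for b in edges:
        adj.setdefault(b.i, []).append(b.j)
        adj.setdefault(b.j, []).append(b.i)
    if any(len(v) != 2 for v in adj.values()):
        return None
    start = edges[0].i
    cyc = [start]
    prev = -1
    while True:
        nxts = [w for w in adj[cyc[-1]] if w != prev]
        nxt = nxts[0] if nxts else adj[cyc[-1]][0]
        if nxt == start:
            break
        prev = cyc[-1]
        cyc.append(nxt)
    return cyc if len(cyc) == len(edges) else None


def _build_assemblies(
    mol: MolecularGraph, sssr: list[list[int]], ring_bonds: set[tuple[int, int]]
) -> list[RingAssembly]:
    # union-find over ring atoms connected by ring bonds
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in ring_bonds:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    groups: dict[int, dict] = {}
    for (i, j) in sorted(ring_bonds):
        root = find(i)
        g = groups.setdefault(root, {"atoms": set(), "bonds": set(), "rings": []})
        g["atoms"].update((i, j))
        g["bonds"].add((i, j))
    for ri, cyc in enumerate(sssr):
        root = find(cyc[0])
        groups[root]["rings"].append(ri)

    return [
        RingAssembly(frozenset(g["atoms"]), frozenset(g["bonds"]), tuple(g["rings"]))
        for _, g in sorted(groups.items())
    ]


# -- graph-symmetry classes ---------------------------------------------------

def symmetry_classes(mol: MolecularGraph) -> list[int]:
    """Atom equivalence classes by iterative neighborhood refinement.

    Morgan-style: start from local invariants (element, charge, H count,
    aromaticity, degree, ring membership) and refine each class by the
    multiset of (neighbor class, bond order, bond aromatic) until stable.
    Used for potential-stereocenter detection.
    """
    labels = [
        (a.symbol, a.charge, a.n_h, a.aromatic, mol.degree(i), a.in_ring)
        for i, a in enumerate(mol.atoms)
    ]
    classes = _relabel(labels)
    for _ in range(mol.n_atoms + 1):
        new = []
        for i in range(mol.n_atoms):
            env = sorted(
                (classes[mol.bonds[bi].other(i)], mol.bonds[bi].order, mol.bonds[bi].aromatic)
                for bi in mol.adjacency()[i]
            )
            new.append((classes[i], tuple(env)))
        new_classes = _relabel(new)
        if len(set(new_classes)) == len(set(classes)):
            return new_classes
        classes = new_classes
    return classes


def _relabel(keys: list) -> list[int]:
    mapping: dict = {}
    for k in sorted(set(keys), key=repr):
        mapping[k] = len(mapping)
    return [mapping[k] for k in keys]
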