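"""PEOE (Gasteiger–Marsili style) partial atomic charges.

Charges are computed on the hydrogen-expanded graph by partial equalization
of orbital electronegativities: each atom carries an electronegativity
polynomial chi(q) = a + b*q + c*q**2; in iteration k a charge increment
proportional to the electronegativity difference across each bond, damped by
``damping_base**k``, flows from the less to the more electronegative atom.
The pairwise transfers conserve total charge exactly. Six damped iterations
(the classical prescription) are run, with an additional convergence check
at tolerance 1e-6 on the largest per-iteration charge move.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigurationError, load
from .molgraph import MolecularGraph


def hybridization(mol: MolecularGraph, idx: int) -> str:
    """sp/sp2/sp3 from bond orders: triple or two doubles -> sp; any double
    or aromatic bond -> sp2; otherwise sp3."""
    doubles = 0
    for bi in mol.adjacency()[idx]:
        b = mol.bonds[bi]
        if b.order == 3:
            return "sp"
        if b.order == 2:
            doubles += 1
        elif b.aromatic:
            doubles = max(doubles, 1)
    if doubles >= 2:
        return "sp"
    if doubles == 1 or mol.atoms[idx].aromatic:
        return "sp2"
    return "sp3"


def peoe_charges(mol: MolecularGraph, tol: float = 1e-6) -> np.ndarray:
    """Partial charges for every atom of ``mol`` (which should already carry
    explicit hydrogens; see ``MolecularGraph.with_explicit_hydrogens``).

    Initial charges are the formal charges; the returned array sums to the
    total formal charge to machine precision.
    """
    cfg = load("peoe")
    params = cfg["parameters"]
    n_iter = int(cfg["iterations"])
    base = float(cfg["damping_base"])
    h_chi_plus = float(cfg["hydrogen_chi_plus"])

    n = mol.n_atoms
    abc = np.empty((n, 3))
    chi_plus = np.empty(n)
    for i, atom in enumerate(mol.atoms):
        try:
            a, b, c = params[atom.symbol][hybridization(mol, i)]
        except KeyError as exc:
            raise ConfigurationError(
                f"no PEOE electronegativity parameters for element {atom.symbol!r}"
            ) from exc
        abc[i] = (a, b, c)
        chi_plus[i] = h_chi_plus if atom.symbol == "H" else a + b + c

    q = np.array([float(a.charge) for a in mol.atoms])
    pairs = [(b.i, b.j) for b in mol.bonds]
    for k in range(1, n_iter + 1):
        damp = base ** k
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        max_move = 0.0
        for i, j in pairs:
            if chi[j] > chi[i]:
                dq = (chi[j] - chi[i]) / chi_plus[i] * damp
                q[i] += dq
                q[j] -= dq
            else:
                dq = (chi[i] - chi[j]) / chi_plus[j] * damp
                q[j] += dq
                q[i] -= dq
            max_move = max(max_move, abs(dq))
        if max_move < tol:
            break
    return q
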