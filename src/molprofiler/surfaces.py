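"""Approximate per-atom surface areas from the 2D graph.

Each atom contributes the area of a sphere of its Bondi van der Waals radius
(plus a 1.4 Å water-probe radius for the accessible variant), reduced by one
spherical cap per bonded neighbor: with radii R1, R2 and the bond length
d approximated by the sum of single-bond covalent radii, the cap hidden on
sphere 1 has height h = R1 - (d^2 + R1^2 - R2^2)/(2d) and area 2*pi*R1*h.
Areas are clamped at zero (heavily substituted atoms can be fully buried).
The scheme is conformation-free and deterministic; its absolute scale is
approximate, which is adequate because the downstream fractional surface
descriptors are ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, load
from .molgraph import MolecularGraph


@dataclass
class AtomAnnotations:
    """Per-atom annotations on a hydrogen-expanded graph."""
    peoe_charge: np.ndarray | None = None
    asa: np.ndarray | None = None   # water-accessible area, A^2
    vsa: np.ndarray | None = None   # van der Waals area, A^2


def _sphere_areas(mol: MolecularGraph, probe: float, vdw: dict, cov: dict) -> np.ndarray:
    n = mol.n_atoms
    radii = np.empty(n)
    for i, a in enumerate(mol.atoms):
        try:
            radii[i] = vdw[a.symbol] + probe
        except KeyError as exc:
            raise ConfigurationError(f"no van der Waals radius for element {a.symbol!r}") from exc
    area = 4.0 * math.pi * radii ** 2
    hidden = np.zeros(n)
    for b in mol.bonds:
        d = cov[mol.atoms[b.i].symbol] + cov[mol.atoms[b.j].symbol]
        for i, j in ((b.i, b.j), (b.j, b.i)):
            r1, r2 = radii[i], radii[j]
            h = r1 - (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
            h = min(max(h, 0.0), 2.0 * r1)
            hidden[i] += 2.0 * math.pi * r1 * h
    return np.maximum(area - hidden, 0.0)


def atom_surfaces(mol: MolecularGraph) -> AtomAnnotations:
    """ASA and VSA per atom of a (hydrogen-expanded) graph."""
    cfg = load("radii")
    vdw, cov = cfg["vdw"], cfg["covalent"]
    probe = float(cfg["probe_radius"])
    return AtomAnnotations(
        asa=_sphere_areas(mol, probe, vdw, cov),
        vsa=_sphere_areas(mol, 0.0, vdw, cov),
    )
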