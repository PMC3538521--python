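"""Shared fixtures: a diverse molecule set, independent oracles, and one
session-scoped synthetic benchmark reused across the heavier tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from molprofiler.descriptors import compute_table
from molprofiler.molgraph import parse_smiles
from molprofiler.screening import ConfusionCounts
from molprofiler.synthetic import generate_labeled_benchmark

#: Diverse, hand-checked structures: hydrocarbons, heteroaromatics, fused /
#: bridged / spiro ring systems, charged species, stereo-rich natural products.
FIXTURE_SMILES = [
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CC(C)(C)C", "CCCCCC",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "c1ccccc1", "Cc1ccccc1", "c1ccncc1", "c1cncnc1", "c1cc[nH]c1",
    "c1ccoc1", "c1ccsc1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
    "c1ccc(-c2ccccc2)cc1", "C1CC2CCC1C2", "C1CCC2CCCCC2C1",
    "C1CCC2(C1)CCCC2", "C1CC2CCC1CC2", "C1C2CC3CC1CC(C2)C3",
    "C1C2C3C1C1C2C3C1",  # cubane: cyclomatic number 5
    "CCO", "CCOCC", "CC(C)O", "CCN", "CC(N)=O", "CC=O", "CC(C)=O",
    "CC(=O)O", "CC(=O)OC", "CC(=O)Cl", "C(Cl)(Cl)Cl", "FC(Cl)Br",
    "C=C", "C=Cc1ccccc1", "CC=CC", "C#N", "CC#N", "N#Cc1ccccc1",
    "C(C(=O)[O-])[NH3+]", "CS(=O)(=O)O", "NS(=O)(=O)c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",                     # aspirin
    "CC(=O)Nc1ccc(O)cc1",                        # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                # ibuprofen
    "OCC1OC(O)C(O)C(O)C1O",                      # glucose (pyranose)
    "CN1C2CCC1CC2",                              # tropane-like
    "O=C1CCCO1", "S1SSSSSSS1",
]


@pytest.fixture(scope="session")
def fixture_mols():
    return [parse_smiles(s) for s in FIXTURE_SMILES]


# -- independent oracles -------------------------------------------------------

def enumerate_subgraph_counts(mol) -> dict[str, int]:
    """Brute-force connected-subgraph census: classify every 2- and 3-edge
    subset of the heavy-atom graph by shape."""
    edges = [(b.i, b.j) for b in mol.bonds]
    sc2 = sc3p = sc3c = sc3ch = 0
    for pair in itertools.combinations(edges, 2):
        nodes = set(pair[0]) | set(pair[1])
        if len(nodes) == 3:  # two edges share exactly one vertex
            sc2 += 1
    for trip in itertools.combinations(edges, 3):
        nodes = sorted(set(trip[0]) | set(trip[1]) | set(trip[2]))
        deg = {n: 0 for n in nodes}
        for u, v in trip:
            deg[u] += 1
            deg[v] += 1
        if len(nodes) == 3 and all(d == 2 for d in deg.values()):
            sc3ch += 1
        elif len(nodes) == 4:
            degs = sorted(deg.values())
            if degs == [1, 1, 1, 3]:
                sc3c += 1
            elif degs == [1, 1, 2, 2] and _connected(trip):
                sc3p += 1
    return {"SC2": sc2, "SC3P": sc3p, "SC3C": sc3c, "SC3CH": sc3ch}


def _connected(edge_subset) -> bool:
    nodes = set()
    for u, v in edge_subset:
        nodes.update((u, v))
    seen = {next(iter(nodes))}
    changed = True
    while changed:
        changed = False
        for u, v in edge_subset:
            if (u in seen) != (v in seen):
                seen.update((u, v))
                changed = True
    return seen == nodes


def brute_force_best_ga(pos: np.ndarray, neg: np.ndarray) -> float:
    """O(n^2) exhaustive threshold scan: every candidate cutoff x both
    directions, strict inequalities, global accuracy."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    pooled = np.unique(np.concatenate([pos, neg]))
    cuts = np.concatenate([[pooled[0] - 1], (pooled[:-1] + pooled[1:]) / 2,
                           [pooled[-1] + 1]])
    best = -1.0
    total = pos.size + neg.size
    for c in cuts:
        for below in (True, False):
            if below:
                tp = (pos < c).sum()
                fp = (neg < c).sum()
            else:
                tp = (pos > c).sum()
                fp = (neg > c).sum()
            ga = (tp + (neg.size - fp)) / total
            best = max(best, ga)
    return best


def metrics_by_hand(cc: ConfusionCounts) -> dict[str, float]:
    """Direct evaluation of the six metric formulas (independent of the
    implementation's code path)."""
    import math
    total = cc.TP + cc.TN + cc.FP + cc.FN
    return {
        "SE": cc.TP / (cc.TP + cc.FN),
        "SP": cc.TN / (cc.TN + cc.FP),
        "PRE1": cc.TP / (cc.TP + cc.FP),
        "PRE2": cc.TN / (cc.TN + cc.FN),
        "GA": (cc.TP + cc.TN) / total,
        "C": (cc.TP * cc.TN - cc.FN * cc.FP)
             / math.sqrt((cc.TP + cc.FN) * (cc.TP + cc.FP)
                         * (cc.TN + cc.FN) * (cc.TN + cc.FP)),
    }


# -- session benchmark ---------------------------------------------------------

BENCHMARK_SEED = 11
BENCHMARK_N = 2000


@pytest.fixture(scope="session")
def benchmark():
    """The three synthetic classes at n=2000/class, fixed seed."""
    return generate_labeled_benchmark(BENCHMARK_N, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_tables(benchmark):
    """Descriptor tables for the session benchmark."""
    return {cls: compute_table(mols) for cls, mols in benchmark.libraries.items()}
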