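"""Library curation: the standard preprocessing protocol for compound sets.

The pipeline mirrors common practice for preparing screening libraries:
(1) drop valence-invalid structures, (2) strip known salt counter-fragments,
(3) drop molecules with elements outside the organic set C,H,O,N,P,S,F,Cl,Br,I,
(4) strip known solvent fragments, (5) keep the largest connected fragment,
(6) deduplicate by canonical (stereo-aware) structure key — plus cross-library
deduplication, an optional reactive-functional-group filter, molecular-weight
cutoffs and MW-distribution-matched subset construction.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rdkit import Chem

from .config import ConfigurationError, load
from .descriptors import count_composition
from .molgraph import ORGANIC_ELEMENTS, MolecularGraph, check_valences, from_rdkit, to_rdkit

STEP_DESCRIPTIONS = {
    1: "bad valence state",
    2: "salt fragment stripped",
    3: "element outside C,H,O,N,P,S,F,Cl,Br,I",
    4: "solvent fragment stripped",
    5: "smaller fragment dropped (largest kept)",
    6: "duplicate within library",
    7: "duplicate across libraries",
}


@dataclass
class CurationReport:
    """Per-step accounting: ``removed[step]`` counts whole molecules removed
    (these sum with ``reactive_removed`` to input − output);
    ``fragment_events[step]`` counts stripped fragments in steps 2/4/5."""
    input_size: int = 0
    output_size: int = 0
    removed: dict[int, int] = field(default_factory=lambda: {k: 0 for k in range(1, 8)})
    fragment_events: dict[int, int] = field(default_factory=lambda: {2: 0, 4: 0, 5: 0})
    reactive_removed: int = 0

    def check(self) -> bool:
        return self.input_size - sum(self.removed.values()) - self.reactive_removed \
            == self.output_size

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "description", "removed_count", "fragment_events"])
            for step in sorted(self.removed):
                w.writerow([step, STEP_DESCRIPTIONS[step], self.removed[step],
                            self.fragment_events.get(step, "")])
            if self.reactive_removed:
                w.writerow(["reactive", "reactive functional group", self.reactive_removed, ""])


@dataclass(frozen=True)
class MWMatchSpec:
    """Parameters for MW-histogram matching.

    ``max_ratio`` caps the subset at that fraction of the candidate set
    (1.0 = no cap beyond per-bin availability)."""
    bin_width: float = 20.0
    rng_seed: int = 0
    max_ratio: float = 1.0

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@functools.lru_cache(maxsize=1)
def _fragment_sets() -> tuple[frozenset[str], frozenset[str]]:
    cfg = load("salts_solvents")

    def canon(smis):
        out = set()
        for s in smis:
            m = Chem.MolFromSmiles(s)
            if m is not None:
                out.add(Chem.MolToSmiles(m))
        return frozenset(out)

    return canon(cfg["salts"]), canon(cfg["solvents"])


@functools.lru_cache(maxsize=1)
def _reactive_patterns() -> list[tuple[str, list[Chem.Mol]]]:
    cfg = load("reactive")["patterns"]
    compiled = []
    for name, patterns in cfg.items():
        mols = []
        for p in patterns:
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise ConfigurationError(f"malformed reactive SMARTS for {name!r}: {p!r}")
            mols.append(q)
        compiled.append((name, mols))
    return compiled


def flag_reactive(mol: MolecularGraph) -> tuple[bool, list[str]]:
    """Match the twelve reactive functional-group classes; returns the hit
    flag and the names of the matched groups."""
    rd = to_rdkit(mol)
    hits = [name for name, queries in _reactive_patterns()
            if any(rd.HasSubstructMatch(q) for q in queries)]
    return bool(hits), hits


def _fragments(mol: MolecularGraph) -> list[str]:
    rd = to_rdkit(mol)
    return [Chem.MolToSmiles(f) for f in Chem.GetMolFrags(rd, asMols=True)]


def curate_library(
    mols: list[MolecularGraph],
    drop_reactive: bool = False,
    exclude_names: set[str] | None = None,
    upstream_rejections: int = 0,
) -> tuple[list[MolecularGraph], CurationReport]:
    """Run the preprocessing protocol on parsed molecules.

    ``upstream_rejections`` counts records that already failed at parse time;
    they are reported as step-1 removals.  ``exclude_names`` is an optional
    name-list exclusion hook (e.g. therapeutic-category exclusions when
    external annotations are available): matching records are dropped before
    the protocol starts and do not appear in the report.
    """
    if exclude_names:
        mols = [m for m in mols if m.name not in exclude_names]

    salts, solvents = _fragment_sets()
    report = CurationReport(input_size=len(mols) + upstream_rejections)
    report.removed[1] = upstream_rejections

    seen: set[str] = set()
    kept: list[MolecularGraph] = []
    for mol in mols:
        # step 1: valence
        if not check_valences(mol):
            report.removed[1] += 1
            continue
        frags = _fragments(mol)
        # step 2: salts (multi-fragment inputs only; the compound itself may
        # coincide with a listed counter-ion, so stripping never empties the
        # record — when every fragment is listed, the largest one is kept)
        remaining = _strip_listed(frags, salts)
        report.fragment_events[2] += len(frags) - len(remaining)
        # step 3: element whitelist
        joined = ".".join(remaining)
        graph = _parse_canonical(joined, mol.name)
        if any(a.symbol not in ORGANIC_ELEMENTS for a in graph.atoms):
            report.removed[3] += 1
            continue
        # step 4: solvents (same stripping rule as step 2)
        frags = _fragments(graph)
        remaining = _strip_listed(frags, solvents)
        report.fragment_events[4] += len(frags) - len(remaining)
        if remaining != frags:
            graph = _parse_canonical(".".join(remaining), mol.name)
        # step 5: largest fragment
        if len(remaining) > 1:
            graph = _parse_canonical(_largest_fragment(remaining), mol.name)
            report.fragment_events[5] += len(remaining) - 1
        # step 6: in-library duplicates (canonical stereo-aware SMILES key)
        key = graph.smiles
        if key in seen:
            report.removed[6] += 1
            continue
        # optional reactive filter
        if drop_reactive and flag_reactive(graph)[0]:
            report.reactive_removed += 1
            continue
        seen.add(key)
        kept.append(graph)

    report.output_size = len(kept)
    assert report.check()
    return kept, report


def _strip_listed(frags: list[str], listed: frozenset[str]) -> list[str]:
    """Drop listed fragments from a multi-fragment record; keep the largest
    fragment if every fragment is listed; never touch single-fragment input."""
    if len(frags) <= 1:
        return frags
    remaining = [f for f in frags if f not in listed]
    if remaining:
        return remaining
    return [_largest_fragment(frags)]


def _largest_fragment(frags: list[str]) -> str:
    def size(smi: str) -> tuple:
        g = _parse_canonical(smi, "")
        return (g.n_atoms, count_composition(g)["MW"], smi)

    return max(frags, key=size)


def _parse_canonical(smiles: str, name: str) -> MolecularGraph:
    rd = Chem.MolFromSmiles(smiles)
    return from_rdkit(rd, name=name)


def cross_deduplicate(
    lib_a: list[MolecularGraph], lib_b: list[MolecularGraph]
) -> list[MolecularGraph]:
    """Remove from ``lib_a`` every structure whose canonical key occurs in
    ``lib_b`` (step 7 of the protocol); ``lib_b`` is untouched."""
    keys_b = {m.smiles for m in lib_b}
    return [m for m in lib_a if m.smiles not in keys_b]


def apply_mw_cutoff(mols: list[MolecularGraph], cutoff: float) -> list[MolecularGraph]:
    """Molecules with MW strictly below ``cutoff`` (average atomic masses)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return [m for m in mols if count_composition(m)["MW"] < cutoff]


def build_mw_matched_subset(
    candidates: list[MolecularGraph],
    reference: list[MolecularGraph],
    spec: MWMatchSpec,
) -> list[MolecularGraph]:
    """Select a subset of ``candidates`` whose MW histogram matches the
    reference's.

    Both sets are binned with ``spec.bin_width``; per bin, candidates are
    sampled without replacement in proportion to the reference bin's relative
    frequency, with the overall scale set so that no bin demands more
    candidates than it has.  Deterministic for a fixed ``rng_seed``.
    """
    if not reference:
        raise ValueError("reference library is empty")
    if not candidates:
        raise ValueError("candidate library is empty")
    cand_mw = np.array([count_composition(m)["MW"] for m in candidates])
    ref_mw = np.array([count_composition(m)["MW"] for m in reference])

    lo = min(cand_mw.min(), ref_mw.min())
    hi = max(cand_mw.max(), ref_mw.max())
    bw = spec.bin_width
    edges = np.arange(np.floor(lo / bw) * bw, np.ceil(hi / bw) * bw + bw, bw)
    cand_bin = np.clip(np.digitize(cand_mw, edges) - 1, 0, len(edges) - 2)
    ref_bin = np.clip(np.digitize(ref_mw, edges) - 1, 0, len(edges) - 2)

    n_bins = len(edges) - 1
    ref_freq = np.bincount(ref_bin, minlength=n_bins) / len(ref_mw)
    cand_count = np.bincount(cand_bin, minlength=n_bins)

    active = ref_freq > 0
    # the scale is set by the scarcest candidate bin among bins where both
    # sets have mass; reference-only bins (typically sparse tails) cannot be
    # served at all and are skipped rather than forcing an empty subset
    servable = active & (cand_count > 0)
    if not servable.any():
        raise ValueError("candidate and reference MW ranges do not overlap")
    scale = float(np.min(cand_count[servable] / ref_freq[servable]))
    scale = min(scale, spec.max_ratio * len(candidates))

    rng = np.random.default_rng(spec.rng_seed)
    selected: list[int] = []
    for b in range(n_bins):
        if not active[b]:
            continue
        take = int(np.floor(scale * ref_freq[b]))
        take = min(take, int(cand_count[b]))
        if take == 0:
            continue
        idx = np.flatnonzero(cand_bin == b)
        chosen = rng.choice(idx, size=take, replace=False)
        selected.extend(int(i) for i in chosen)
    selected.sort()
    return [candidates[i] for i in selected]
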