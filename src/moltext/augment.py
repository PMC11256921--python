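"""Molecular graph augmentations with RMSD-gated acceptance.

Four augmentation kinds produce semantically consistent variants of a
molecule for contrastive pretraining:

* ``node_drop``             — remove ceil(fraction * a) atoms (default 10%),
                              resampling until the remainder stays connected;
* ``subgraph``              — induced subgraph on the atoms visited by a
                              seeded random walk;
* ``chem_transform``        — add or remove one small functional group
                              (methyl, hydroxyl, fluoro, chloro, amino) at a
                              uniformly chosen legal site;
* ``substructure_removal``  — cleave one BRICS bond and discard the smaller
                              fragment.

Every augmented graph is re-embedded in 3D and compared with the original by
an MCS-mapped, Kabsch-aligned coordinate RMSD (Angstrom); candidates are
accepted when that dissimilarity falls below a threshold (default 3.0 A),
retrying with fresh sub-seeds otherwise.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS, rdFMCS, rdMolAlign

from .errors import AugmentationInfeasibleError, StateError
from .molgraph import (
    MolecularGraph,
    from_rdkit,
    generate_conformer,
    to_rdkit,
)

KINDS = ("node_drop", "subgraph", "chem_transform", "substructure_removal")
DEFAULT_THRESHOLD = 3.0   # Angstrom
FUNCTIONAL_GROUPS = ("C", "O", "F", "Cl", "N")   # methyl/hydroxyl/F/Cl/amino


@dataclass
class AugmentationResult:
    graph: MolecularGraph
    kind: str
    dissimilarity: float
    accepted: bool
    attempts: int


@dataclass
class AugmentationSet:
    """Exactly one result per augmentation kind (the four training views)."""

    members: dict

    def __post_init__(self):
        if set(self.members) != set(KINDS):
            raise ValueError(f"need exactly the four kinds {KINDS}")

    def graphs(self) -> list:
        return [self.members[k].graph for k in KINDS]


def _subseed(seed: int, *salt) -> int:
    ss = np.random.SeedSequence([int(seed) % 2**31, *[int(s) % 2**31 for s in salt]])
    return int(ss.generate_state(1)[0] % 2**31)


def _ensure_coords(graph: MolecularGraph, seed: int) -> MolecularGraph:
    if graph.coords is not None:
        return graph
    return generate_conformer(graph, _subseed(seed, 0xC0))


def _delete_atoms(mol: Chem.Mol, idxs) -> Chem.Mol:
    """Remove atoms from a kekulized copy and re-sanitize (implicit-H repair)."""
    rw = Chem.RWMol(mol)
    Chem.Kekulize(rw, clearAromaticFlags=True)
    for i in sorted(idxs, reverse=True):
        rw.RemoveAtom(int(i))
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _connected(adj: dict, keep: set) -> bool:
    start = next(iter(keep))
    seen = {start}
    q = deque([start])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v in keep and v not in seen:
                seen.add(v)
                q.append(v)
    return len(seen) == len(keep)


def _finish(original: MolecularGraph, mol: Chem.Mol, kind: str, seed: int,
            attempts: int, threshold: float = DEFAULT_THRESHOLD) -> AugmentationResult:
    g = from_rdkit(mol)
    g = generate_conformer(g, _subseed(seed, 0x3D))
    d = dissimilarity(original, g)
    return AugmentationResult(g, kind, d, bool(d < threshold), attempts)


# ---------------------------------------------------------------------------
# The four augmentations
# ---------------------------------------------------------------------------

def node_drop(graph: MolecularGraph, fraction: float = 0.1,
              seed: int = 0) -> AugmentationResult:
    """Drop ceil(fraction*a) atoms uniformly; keep the graph connected."""
    a = graph.atom_count
    if a < 3:
        raise AugmentationInfeasibleError(f"node_drop needs >=3 atoms, got {a}")
    n_drop = math.ceil(fraction * a)
    if n_drop == 0:
        return AugmentationResult(graph, "node_drop", 0.0, True, 1)
    if n_drop >= a:
        raise AugmentationInfeasibleError("fraction would drop every atom")
    original = _ensure_coords(graph, seed)
    rng = np.random.default_rng(_subseed(seed, 1))
    adj = graph.adjacency()
    for attempt in range(1, 21):
        drop = set(rng.choice(a, size=n_drop, replace=False).tolist())
        keep = set(range(a)) - drop
        if not _connected(adj, keep):
            continue
        try:
            mol = _delete_atoms(to_rdkit(graph), drop)
        except Exception:
            continue
        return _finish(original, mol, "node_drop", seed, attempt)
    raise AugmentationInfeasibleError(
        "no connected valence-valid node drop in 20 resamples")


def subgraph_sample(graph: MolecularGraph, target_fraction: float = 0.8,
                    seed: int = 0) -> AugmentationResult:
    """Induced subgraph on the atoms visited by a seeded random walk."""
    a = graph.atom_count
    if a < 3:
        raise AugmentationInfeasibleError(f"subgraph needs >=3 atoms, got {a}")
    original = _ensure_coords(graph, seed)
    rng = np.random.default_rng(_subseed(seed, 2))
    adj = graph.adjacency()
    target = math.ceil(target_fraction * a)
    cur = int(rng.integers(a))
    visited = {cur}
    for _ in range(10 * a):
        if len(visited) >= target:
            break
        nbrs = adj[cur]
        if not nbrs:
            break
        cur = int(nbrs[rng.integers(len(nbrs))])
        visited.add(cur)
    drop = set(range(a)) - visited
    if not drop:
        return AugmentationResult(original, "subgraph", 0.0, True, 1)
    try:
        mol = _delete_atoms(to_rdkit(graph), drop)
    except Exception as exc:
        raise AugmentationInfeasibleError(
            f"random-walk subgraph is not a valid molecule: {exc}") from exc
    return _finish(original, mol, "subgraph", seed, 1)


def chemical_transform(graph: MolecularGraph, seed: int = 0,
                       ops: tuple = ("add", "remove")) -> AugmentationResult:
    """Add or remove one functional group at a uniformly chosen legal site."""
    mol = to_rdkit(graph)
    moves = []
    if "add" in ops:
        for atom in mol.GetAtoms():
            if atom.GetTotalNumHs() >= 1:
                for grp in FUNCTIONAL_GROUPS:
                    moves.append(("add", atom.GetIdx(), grp))
    if "remove" in ops and mol.GetNumAtoms() >= 2:
        for atom in mol.GetAtoms():
            if (atom.GetDegree() == 1 and atom.GetFormalCharge() == 0
                    and atom.GetSymbol() in FUNCTIONAL_GROUPS):
                moves.append(("remove", atom.GetIdx(), atom.GetSymbol()))
    if not moves:
        raise AugmentationInfeasibleError(
            f"no legal functional-group move among ops={ops}")
    original = _ensure_coords(graph, seed)
    rng = np.random.default_rng(_subseed(seed, 3))
    op, site, grp = moves[int(rng.integers(len(moves)))]
    if op == "add":
        rw = Chem.RWMol(mol)
        site_atom = rw.GetAtomWithIdx(int(site))
        if site_atom.GetNumExplicitHs() > 0:   # e.g. aromatic [nH]
            site_atom.SetNumExplicitHs(site_atom.GetNumExplicitHs() - 1)
        new_idx = rw.AddAtom(Chem.Atom(grp))
        rw.AddBond(int(site), new_idx, Chem.BondType.SINGLE)
        product = rw.GetMol()
        try:
            Chem.SanitizeMol(product)
        except Exception as exc:
            raise AugmentationInfeasibleError(
                f"functional-group addition failed sanitization: {exc}") from exc
    else:
        try:
            product = _delete_atoms(mol, [site])
        except Exception as exc:
            raise AugmentationInfeasibleError(
                f"functional-group removal failed sanitization: {exc}") from exc
    return _finish(original, product, "chem_transform", seed, 1)


def substructure_remove(graph: MolecularGraph, seed: int = 0) -> AugmentationResult:
    """Cleave one BRICS bond; discard the smaller fragment, keep >=3 atoms."""
    mol = to_rdkit(graph)
    brics = sorted({tuple(sorted(b)) for b, _ in BRICS.FindBRICSBonds(mol)})
    if not brics:
        raise AugmentationInfeasibleError("molecule has no BRICS-cleavable bonds")
    adj = graph.adjacency()
    a = graph.atom_count
    candidates = []
    for i, j in brics:
        # component of i with the i-j bond removed
        seen = {i}
        q = deque([i])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if (u, v) in ((i, j), (j, i)):
                    continue
                if v not in seen:
                    seen.add(v)
                    q.append(v)
        comp_i = seen
        comp_j = set(range(a)) - comp_i
        small, big = sorted((comp_i, comp_j), key=lambda c: (len(c), min(c)))
        if len(big) >= 3:
            candidates.append(((i, j), small))
    if not candidates:
        raise AugmentationInfeasibleError(
            "every BRICS cleavage leaves fewer than 3 retained atoms")
    original = _ensure_coords(graph, seed)
    rng = np.random.default_rng(_subseed(seed, 4))
    _, small = candidates[int(rng.integers(len(candidates)))]
    try:
        product = _delete_atoms(mol, small)
    except Exception as exc:
        raise AugmentationInfeasibleError(
            f"BRICS fragment removal failed sanitization: {exc}") from exc
    return _finish(original, product, "substructure_removal", seed, 1)


_OPS = {
    "node_drop": lambda g, s: node_drop(g, seed=s),
    "subgraph": lambda g, s: subgraph_sample(g, seed=s),
    "chem_transform": lambda g, s: chemical_transform(g, seed=s),
    "substructure_removal": lambda g, s: substructure_remove(g, seed=s),
}


# ---------------------------------------------------------------------------
# Dissimilarity and the acceptance loop
# ---------------------------------------------------------------------------

def dissimilarity(original: MolecularGraph, augmented: MolecularGraph) -> float:
    """MCS-mapped, optimally superposed coordinate RMSD in Angstrom.

    Atom correspondence comes from a maximum-common-substructure search
    (>= 3 mapped atoms required, else +inf); the rigid-body alignment and
    RMSD use RDKit's Kabsch-based AlignMol over the mapped atoms.
    """
    if original.coords is None or augmented.coords is None:
        raise StateError("dissimilarity needs 3D coordinates on both graphs")
    ref = to_rdkit(original, with_coords=True)
    prb = to_rdkit(augmented, with_coords=True)
    mcs = rdFMCS.FindMCS([ref, prb], timeout=10)
    if mcs.numAtoms < 3:
        return float("inf")
    patt = Chem.MolFromSmarts(mcs.smartsString)
    m_ref = ref.GetSubstructMatch(patt)
    m_prb = prb.GetSubstructMatch(patt)
    if len(m_ref) < 3 or len(m_prb) < 3:
        return float("inf")
    return float(rdMolAlign.AlignMol(
        prb, ref, atomMap=list(zip(m_prb, m_ref))))


def augment_accepted(graph: MolecularGraph, kind: str,
                     threshold: float = DEFAULT_THRESHOLD,
                     max_tries: int = 10, seed: int = 0) -> AugmentationResult:
    """First candidate under the threshold, else the least-dissimilar one."""
    if kind not in _OPS:
        raise ValueError(f"unknown augmentation kind {kind!r}; valid: {KINDS}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if max_tries < 1:
        raise ValueError("max_tries must be >= 1")
    graph = _ensure_coords(graph, seed)   # one reference geometry for all tries
    best = None
    failures = []
    for t in range(max_tries):
        try:
            cand = _OPS[kind](graph, _subseed(seed, 10 + t))
        except AugmentationInfeasibleError as exc:
            failures.append(exc)
            continue
        cand.attempts = t + 1
        if cand.dissimilarity < threshold:
            cand.accepted = True
            return cand
        if best is None or cand.dissimilarity < best.dissimilarity:
            best = cand
    if best is None:
        raise AugmentationInfeasibleError(
            f"{kind} infeasible in all {max_tries} tries: {failures[-1]}")
    best.accepted = False
    return best


def build_augmentation_set(graph: MolecularGraph, seed: int = 0,
                           threshold: float = DEFAULT_THRESHOLD,
                           max_tries: int = 10) -> AugmentationSet:
    """One accepted-or-fallback result per kind; chemistry kinds that are
    infeasible fall back to node_drop under a distinct sub-seed so the set
    always has exactly four members."""
    graph = _ensure_coords(graph, seed)
    members = {}
    for idx, kind in enumerate(KINDS):
        try:
            res = augment_accepted(graph, kind, threshold, max_tries,
                                   _subseed(seed, 100 + idx))
        except AugmentationInfeasibleError:
            if kind == "node_drop":
                raise
            res = augment_accepted(graph, "node_drop", threshold, max_tries,
                                   _subseed(seed, 200 + idx))
            res = AugmentationResult(res.graph, kind, res.dissimilarity,
                                     res.accepted, res.attempts)
        members[kind] = res
    return AugmentationSet(members)
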