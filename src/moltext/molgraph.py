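"""Molecular graph data model, SMILES/SDF I/O and shortest-path machinery.

Graphs are heavy-atom graphs (hydrogens implicit), 0-based indexed, with
undirected bonds stored once. Each bond carries a fixed-width binary feature
vector describing the bond (order one-hots, ring membership, conjugation).
3D coordinates, when present, are an (a, 3) array in Angstrom.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .errors import (
    ConformerError,
    FormatError,
    SmilesParseError,
    StateError,
    ValenceError,
)

RDLogger.DisableLog("rdApp.*")

_BOND_ORDER_SLOTS = ("single", "double", "triple", "aromatic")


@dataclass(frozen=True)
class EdgeFeatureSchema:
    """Layout of the per-bond binary feature vector.

    Default layout (k_edge=6): 4 one-hot bond-order slots
    (single/double/triple/aromatic), an in-ring flag and a conjugation flag.
    """

    slots: tuple = _BOND_ORDER_SLOTS + ("in_ring", "conjugated")

    @property
    def k_edge(self) -> int:
        return len(self.slots)

    def encode(self, bond: Chem.Bond) -> np.ndarray:
        v = np.zeros(self.k_edge, dtype=float)
        order = {
            Chem.BondType.SINGLE: 0,
            Chem.BondType.DOUBLE: 1,
            Chem.BondType.TRIPLE: 2,
            Chem.BondType.AROMATIC: 3,
        }.get(bond.GetBondType())
        if order is None:
            # dative/other orders collapse onto single for the one-hot
            order = 0
        v[order] = 1.0
        if bond.IsInRing():
            v[4] = 1.0
        if bond.GetIsConjugated():
            v[5] = 1.0
        return v


DEFAULT_SCHEMA = EdgeFeatureSchema()


@dataclass(frozen=True)
class AtomRecord:
    element: str
    formal_charge: int
    degree: int


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    features: np.ndarray
    order: float = 1.0  # 1, 2, 3 or 1.5 (aromatic); used to rebuild molecules


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with optional 3D coordinates."""

    atoms: list
    bonds: list
    coords: np.ndarray | None = None
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    @property
    def k_edge(self) -> int:
        if not self.bonds:
            return DEFAULT_SCHEMA.k_edge
        return len(self.bonds[0].features)

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        a = self.atom_count
        seen = set()
        k = self.k_edge
        for b in self.bonds:
            if not (0 <= b.i < a and 0 <= b.j < a):
                raise ValueError(f"bond ({b.i},{b.j}) out of range for {a} atoms")
            if b.i == b.j:
                raise ValueError(f"self-loop on atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            if len(b.features) != k:
                raise ValueError("inconsistent edge feature dimension")
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (a, 3) or not np.all(np.isfinite(c)):
                raise ValueError(f"coords must be a finite ({a}, 3) array")

    def adjacency(self) -> dict:
        adj: dict = {i: [] for i in range(self.atom_count)}
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        for i in adj:
            adj[i].sort()
        return adj

    def bond_lookup(self) -> dict:
        return {(min(b.i, b.j), max(b.i, b.j)): b for b in self.bonds}


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------

def from_rdkit(mol: Chem.Mol, schema: EdgeFeatureSchema = DEFAULT_SCHEMA,
               keep_coords: bool = False) -> MolecularGraph:
    """Build a MolecularGraph from a sanitized, hydrogen-implicit RDKit Mol."""
    atoms = []
    for at in mol.GetAtoms():
        atoms.append(AtomRecord(at.GetSymbol(), at.GetFormalCharge(), at.GetDegree()))
    bonds = []
    for bd in mol.GetBonds():
        i, j = bd.GetBeginAtomIdx(), bd.GetEndAtomIdx()
        i, j = (i, j) if i < j else (j, i)
        bonds.append(Bond(i, j, schema.encode(bd), bd.GetBondTypeAsDouble()))
    coords = None
    if keep_coords and mol.GetNumConformers() > 0:
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    g = MolecularGraph(atoms, bonds, coords, mol=Chem.Mol(mol))
    g.validate()
    return g


_BOND_TYPES = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
               3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}


def to_rdkit(graph: MolecularGraph, with_coords: bool = False) -> Chem.Mol:
    """RDKit Mol for a graph; uses the cached molecule when available."""
    if graph.mol is not None:
        mol = Chem.Mol(graph.mol)
    else:
        rw = Chem.RWMol()
        for at in graph.atoms:
            a = Chem.Atom(at.element)
            a.SetFormalCharge(at.formal_charge)
            rw.AddAtom(a)
        for b in graph.bonds:
            rw.AddBond(b.i, b.j, _BOND_TYPES.get(b.order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - rdkit raises various types
            raise ValenceError(f"graph is not a valid molecule: {exc}") from exc
    if with_coords:
        if graph.coords is None:
            raise StateError("graph has no coordinates; run generate_conformer first")
        conf = Chem.Conformer(graph.atom_count)
        for i, xyz in enumerate(np.asarray(graph.coords, dtype=float)):
            conf.SetAtomPosition(i, tuple(float(x) for x in xyz))
        mol.RemoveAllConformers()
        mol.AddConformer(conf, assignId=True)
    return mol


def to_smiles(graph: MolecularGraph) -> str:
    return Chem.MolToSmiles(to_rdkit(graph))


def validate_valence(graph: MolecularGraph) -> None:
    """Raise ValenceError if the graph does not sanitize as a molecule."""
    mol = to_rdkit(graph)
    try:
        Chem.SanitizeMol(Chem.Mol(mol))
    except Exception as exc:
        raise ValenceError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def parse_smiles(smiles: str, schema: EdgeFeatureSchema = DEFAULT_SCHEMA) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom MolecularGraph (no coords)."""
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ValenceError(f"SMILES {smiles!r} fails valence checks: {exc}") from exc
    return from_rdkit(mol, schema)


def generate_conformer(graph: MolecularGraph, seed: int,
                       max_attempts: int = 10) -> MolecularGraph:
    """Distance-geometry embed + MMFF94 minimize; deterministic in (graph, seed).

    Hydrogens are added for the embedding and stripped afterwards; only
    heavy-atom coordinates are stored. Retries the embedding with derived
    seeds up to ``max_attempts`` times before raising ConformerError.
    """
    if graph.atom_count < 1:
        raise ValueError("graph must have at least one atom")
    base = to_rdkit(graph)
    molh = Chem.AddHs(base)
    conf_id = -1
    attempts = 0
    for attempt in range(max_attempts):
        attempts = attempt + 1
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) % (2**31 - 1) + attempt * 7919
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise ConformerError(
            f"3D embedding failed after {attempts} attempts", attempts=attempts)
    try:
        AllChem.MMFFOptimizeMolecule(molh, mmffVariant="MMFF94", maxIters=500)
    except Exception:
        pass  # an unoptimized conformer is still a valid geometry
    molh = Chem.RemoveHs(molh)
    coords = np.array(molh.GetConformer().GetPositions(), dtype=float)
    out = replace(graph, coords=coords, mol=Chem.Mol(molh))
    out.validate()
    return out


def permute_atoms(graph: MolecularGraph, perm) -> MolecularGraph:
    """Renumber atoms: old index i becomes perm[i]. Coordinates follow atoms."""
    perm = np.asarray(perm, dtype=int)
    a = graph.atom_count
    if sorted(perm.tolist()) != list(range(a)):
        raise ValueError("perm must be a permutation of 0..a-1")
    atoms = [None] * a
    for i, at in enumerate(graph.atoms):
        atoms[perm[i]] = at
    bonds = []
    for b in graph.bonds:
        i, j = int(perm[b.i]), int(perm[b.j])
        i, j = (i, j) if i < j else (j, i)
        bonds.append(Bond(i, j, b.features.copy(), b.order))
    coords = None
    if graph.coords is not None:
        coords = np.empty_like(np.asarray(graph.coords, dtype=float))
        coords[perm] = graph.coords
    mol = None
    if graph.mol is not None:
        # RenumberAtoms takes newOrder with newOrder[newIdx] = oldIdx
        inv = np.empty(a, dtype=int)
        inv[perm] = np.arange(a)
        mol = Chem.RenumberAtoms(graph.mol, [int(x) for x in inv])
    g = MolecularGraph(atoms, bonds, coords, mol=mol)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Shortest-path machinery
# ---------------------------------------------------------------------------

def spd_matrix(graph: MolecularGraph) -> np.ndarray:
    """Unweighted shortest-path (bond-count) distances, shape (a, a) int.

    Unreachable pairs carry the sentinel value a (the atom count), which
    exceeds any realizable path length.
    """
    a = graph.atom_count
    if a == 0:
        return np.zeros((0, 0), dtype=int)
    rows, cols = [], []
    for b in graph.bonds:
        rows += [b.i, b.j]
        cols += [b.j, b.i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(a, a))
    dist = _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)
    dist[~np.isfinite(dist)] = a
    return dist.astype(int)


def _bfs_parents(graph: MolecularGraph, source: int) -> list:
    """BFS tree from source, expanding neighbors in ascending index order."""
    adj = graph.adjacency()
    parent = [-1] * graph.atom_count
    seen = {source}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                q.append(v)
    return parent


def shortest_path_edge_features(graph: MolecularGraph, i: int, j: int) -> list:
    """Edge feature vectors along the canonical shortest path between i and j.

    The query is normalized to (min(i,j), max(i,j)) so the result is symmetric.
    Among equal-length shortest paths, the breadth-first path that expands
    neighbors in ascending atom-index order is returned. Empty list for i == j
    or unreachable pairs.
    """
    a = graph.atom_count
    if not (0 <= i < a and 0 <= j < a):
        raise IndexError(f"atom index out of range: ({i}, {j}) for {a} atoms")
    if i == j:
        return []
    s, t = (i, j) if i < j else (j, i)
    parent = _bfs_parents(graph, s)
    if parent[t] == -1 and t != s:
        return []
    path = [t]
    while path[-1] != s:
        path.append(parent[path[-1]])
    path.reverse()
    lut = graph.bond_lookup()
    return [lut[(min(u, v), max(u, v))].features
            for u, v in zip(path[:-1], path[1:])]


def path_averaged_edge_features(graph: MolecularGraph) -> np.ndarray:
    """(a, a, k_edge) tensor of edge features averaged over all shortest paths.

    Entry (i, j) is the element-wise mean of the bond feature vectors along a
    shortest i-j path, averaged uniformly over every shortest path (dynamic
    program over the shortest-path DAG). This makes the quantity independent
    of atom numbering. Zero vector for i == j and unreachable pairs.
    """
    a = graph.atom_count
    k = graph.k_edge
    out = np.zeros((a, a, k), dtype=float)
    if a == 0 or not graph.bonds:
        return out
    adj = graph.adjacency()
    lut = graph.bond_lookup()
    for s in range(a):
        dist = np.full(a, -1, dtype=int)
        dist[s] = 0
        order = [s]
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    order.append(v)
                    q.append(v)
        sigma = np.zeros(a)          # number of shortest s-v paths
        fsum = np.zeros((a, k))      # sum over those paths of summed features
        sigma[s] = 1.0
        for v in order:
            if v == s:
                continue
            for u in adj[v]:
                if dist[u] == dist[v] - 1:
                    e = lut[(min(u, v), max(u, v))].features
                    sigma[v] += sigma[u]
                    fsum[v] += fsum[u] + sigma[u] * e
        for t in range(a):
            if t != s and dist[t] > 0:
                out[s, t] = fsum[t] / (sigma[t] * dist[t])
    return out


# ---------------------------------------------------------------------------
# SDF I/O
# ---------------------------------------------------------------------------

def write_sdf(graph: MolecularGraph, path) -> None:
    """Write one SDF (V2000) record; 3D when coordinates are present."""
    mol = to_rdkit(graph, with_coords=graph.coords is not None)
    writer = Chem.SDWriter(str(path))
    try:
        writer.write(mol)
    finally:
        writer.close()


def read_sdf(path, schema: EdgeFeatureSchema = DEFAULT_SCHEMA) -> list:
    """Read all records of an SDF file as MolecularGraphs (coords kept)."""
    import os

    if not os.path.exists(path):
        raise FormatError(f"no such SDF file: {path}")
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty SDF file (line 1)")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    graphs = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            # locate the offending record for the error message
            line = text[: _record_offset(text, idx)].count("\n") + 1
            raise FormatError(f"{path}: malformed SDF record {idx + 1} (near line {line})")
        keep = mol.GetNumConformers() > 0 and mol.GetConformer().Is3D()
        graphs.append(from_rdkit(mol, schema, keep_coords=keep))
    if not graphs:
        raise FormatError(f"{path}: no molecule records found (line 1)")
    return graphs


def _record_offset(text: str, idx: int) -> int:
    pos = 0
    for _ in range(idx):
        nxt = text.find("$$$$", pos)
        if nxt < 0:
            return len(text)
        pos = nxt + 4
    return pos


def sdf_roundtrip(graph: MolecularGraph, path) -> MolecularGraph:
    """Write the graph to SDF and read it back (first record)."""
    write_sdf(graph, path)
    return read_sdf(path)[0]
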