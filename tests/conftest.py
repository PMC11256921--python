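import numpy as np
import pytest

from moltext.encoders import EncoderConfig, ModelWeights
from moltext.fixtures import make_toy_corpus
from moltext.molgraph import AtomRecord, Bond, MolecularGraph, generate_conformer, parse_smiles


@pytest.fixture(scope="session")
def aspirin():
    return generate_conformer(parse_smiles("CC(=O)Oc1ccccc1C(=O)O"), seed=7)


@pytest.fixture(scope="session")
def benzene():
    return generate_conformer(parse_smiles("c1ccccc1"), seed=7)


@pytest.fixture(scope="session")
def small_corpus():
    """Ten conformer-bearing molecules with templated captions."""
    return make_toy_corpus(10, seed=2)


@pytest.fixture(scope="session")
def default_weights():
    return ModelWeights.init(EncoderConfig(), seed=0)


def make_random_graph(rng, max_atoms=12, k_edge=6, connected=True):
    """Chemistry-free random graph with one-hot-style bond features."""
    a = int(rng.integers(2, max_atoms + 1))
    bonds = []
    seen = set()
    if connected:
        order = rng.permutation(a)
        for i in range(1, a):
            u, v = int(order[i]), int(order[int(rng.integers(i))])
            u, v = min(u, v), max(u, v)
            seen.add((u, v))
    n_extra = int(rng.integers(0, a))
    for _ in range(n_extra):
        u, v = rng.integers(a), rng.integers(a)
        u, v = int(min(u, v)), int(max(u, v))
        if u != v:
            seen.add((u, v))
    for (u, v) in sorted(seen):
        feat = np.zeros(k_edge)
        feat[int(rng.integers(4))] = 1.0
        feat[4:] = rng.integers(0, 2, size=k_edge - 4)
        bonds.append(Bond(u, v, feat))
    deg = np.zeros(a, dtype=int)
    for b in bonds:
        deg[b.i] += 1
        deg[b.j] += 1
    atoms = [AtomRecord("C", 0, int(d)) for d in deg]
    g = MolecularGraph(atoms, bonds)
    g.validate()
    return g


def floyd_warshall_oracle(graph):
    """Independent all-pairs shortest-path oracle (triple loop)."""
    a = graph.atom_count
    INF = 10**9
    d = np.full((a, a), INF, dtype=np.int64)
    np.fill_diagonal(d, 0)
    for b in graph.bonds:
        d[b.i, b.j] = d[b.j, b.i] = 1
    for k in range(a):
        for i in range(a):
            for j in range(a):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    d[d >= INF] = a
    return d
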