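"""Synthetic molecule-text corpus generation.

A built-in list of ~45 small drug-like molecules (fast conformers, diverse
functional groups) is paired with three templated captions per molecule
filled from computed descriptor values, so captions genuinely correlate
with structure. The corpus emulates curated molecule-description pairings
at desk scale; it does not reproduce literature text mining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from rdkit.Chem import rdMolDescriptors

from .augment import chemical_transform
from .molgraph import MolecularGraph, generate_conformer, parse_smiles, to_rdkit, to_smiles
from .tasks import property_panel

BUILTIN_SMILES = (
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "c1ccccc1",                         # benzene
    "Cc1ccccc1",                        # toluene
    "Oc1ccccc1",                        # phenol
    "Nc1ccccc1",                        # aniline
    "O=C(O)c1ccccc1",                   # benzoic acid
    "O=C(O)c1ccccc1O",                  # salicylic acid
    "CN1CCCC1c1cccnc1",                 # nicotine
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",     # naproxen
    "COc1cc(C=O)ccc1O",                 # vanillin
    "c1ccncc1",                         # pyridine
    "c1ccc2[nH]ccc2c1",                 # indole
    "c1c[nH]cn1",                       # imidazole
    "c1ccoc1",                          # furan
    "c1ccsc1",                          # thiophene
    "C1CCCCC1",                         # cyclohexane
    "Nc1ncnc2[nH]cnc12",                # adenine
    "O=c1cc[nH]c(=O)[nH]1",             # uracil
    "Cc1c[nH]c(=O)[nH]c1=O",            # thymine
    "OCC1OC(O)C(O)C(O)C1O",             # glucose (pyranose)
    "OC(=O)CC(O)(C(=O)O)CC(=O)O",       # citric acid
    "CC(O)C(=O)O",                      # lactic acid
    "CC(N)C(=O)O",                      # alanine
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "NC(Cc1ccc(O)cc1)C(=O)O",           # tyrosine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",      # tryptophan
    "NCCc1c[nH]c2ccc(O)cc12",           # serotonin
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "CNCC(O)c1ccc(O)c(O)c1",            # adrenaline
    "CC(C)=O",                          # acetone
    "CC(=O)O",                          # acetic acid
    "NC(=O)c1cccnc1",                   # nicotinamide
    "O=Cc1ccccc1",                      # benzaldehyde
    "C=Cc1ccccc1",                      # styrene
    "COc1ccccc1",                       # anisole
    "Oc1ccccc1O",                       # catechol
    "Oc1cccc(O)c1",                     # resorcinol
    "O=C(O)/C=C/c1ccccc1",              # cinnamic acid
    "CC(C)C1CCC(C)CC1O",                # menthol
    "Cn1cnc2c1c(=O)[nH]c(=O)n2C",       # theobromine
    "O=C1NS(=O)(=O)c2ccccc12",          # saccharin
    "O=c1ccc2ccccc2o1",                 # coumarin
)


@dataclass
class ToyCorpus:
    pairs: list        # (MolecularGraph with coords, [caption x3])
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)


def make_captions(graph: MolecularGraph) -> list:
    """Three caption variants filled from computed descriptors."""
    p = property_panel(graph)
    formula = rdMolDescriptors.CalcMolFormula(to_rdkit(graph))
    return [
        (f"This molecule has {p.hba} hydrogen bond acceptors and "
         f"{p.hbd} hydrogen bond donors."),
        (f"A compound with topological polar surface area {p.tpsa:.1f} and "
         f"Wildman-Crippen logP {p.wclogp:.2f}."),
        (f"Drug-likeness QED {p.qed:.2f}; formula {formula} with "
         f"{graph.atom_count} heavy atoms."),
    ]


def make_toy_corpus(n: int, seed: int = 0) -> ToyCorpus:
    """Sample n conformer-bearing molecules with 3 captions each.

    When n exceeds the built-in list, extra diversity comes from seeded
    functional-group transformations of randomly chosen base molecules.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = list(BUILTIN_SMILES)
    order = rng.permutation(len(base))
    chosen = [base[i] for i in order[:min(n, len(base))]]
    graphs = []
    for i, smi in enumerate(chosen):
        g = parse_smiles(smi)
        graphs.append(generate_conformer(g, seed=int((seed + 1) * 1009 + i) % 2**31))
    while len(graphs) < n:
        idx = int(rng.integers(len(graphs)))
        try:
            res = chemical_transform(graphs[idx],
                                     seed=int(rng.integers(2**31)))
            graphs.append(res.graph)
        except Exception:
            continue
    pairs = [(g, make_captions(g)) for g in graphs]
    return ToyCorpus(pairs=pairs, seed=seed)


def save_corpus_jsonl(corpus: ToyCorpus, path) -> None:
    with open(path, "w") as fh:
        for g, captions in corpus.pairs:
            fh.write(json.dumps({"smiles": to_smiles(g),
                                 "captions": captions}) + "\n")


def load_corpus_jsonl(path, conformer_seed: int = 0) -> ToyCorpus:
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            rec = json.loads(line)
            g = generate_conformer(parse_smiles(rec["smiles"]),
                                   seed=(conformer_seed * 131 + i) % 2**31)
            pairs.append((g, list(rec["captions"])))
    return ToyCorpus(pairs=pairs, seed=conformer_seed)
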