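"""Augmentation kinds, RMSD dissimilarity and the acceptance loop."""

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import BRICS

from moltext.augment import (
    KINDS,
    augment_accepted,
    build_augmentation_set,
    chemical_transform,
    dissimilarity,
    node_drop,
    subgraph_sample,
    substructure_remove,
)
from moltext.errors import AugmentationInfeasibleError, StateError
from moltext.molgraph import (
    generate_conformer,
    parse_smiles,
    to_rdkit,
    to_smiles,
    validate_valence,
)


class TestNodeDrop:
    def test_exact_drop_count(self):
        g = generate_conformer(parse_smiles("CCCCCCCCCC"), seed=1)  # a=10
        res = node_drop(g, fraction=0.1, seed=4)
        assert res.graph.atom_count == 9

    def test_ceil_rounding(self, aspirin):
        res = node_drop(aspirin, fraction=0.1, seed=1)
        assert res.graph.atom_count == aspirin.atom_count - math.ceil(
            0.1 * aspirin.atom_count)

    def test_zero_fraction_noop(self, aspirin):
        res = node_drop(aspirin, fraction=0.0, seed=0)
        assert res.graph.atom_count == aspirin.atom_count
        assert res.dissimilarity == 0.0

    def test_deterministic(self, aspirin):
        r1 = node_drop(aspirin, seed=9)
        r2 = node_drop(aspirin, seed=9)
        assert to_smiles(r1.graph) == to_smiles(r2.graph)
        assert np.array_equal(r1.graph.coords, r2.graph.coords)

    def test_too_small(self):
        g = parse_smiles("CC")
        with pytest.raises(AugmentationInfeasibleError):
            node_drop(g, seed=0)


class TestSubgraphSample:
    def test_nodes_subset_and_connected(self, aspirin):
        res = subgraph_sample(aspirin, target_fraction=0.6, seed=2)
        assert res.graph.atom_count <= aspirin.atom_count
        validate_valence(res.graph)

    def test_full_fraction_recovers_whole_path_graph(self):
        g = generate_conformer(parse_smiles("CCCCC"), seed=1)
        res = subgraph_sample(g, target_fraction=1.0, seed=3)
        assert res.graph.atom_count == 5

    def test_deterministic(self, aspirin):
        r1 = subgraph_sample(aspirin, seed=5)
        r2 = subgraph_sample(aspirin, seed=5)
        assert to_smiles(r1.graph) == to_smiles(r2.graph)


class TestChemicalTransform:
    def test_benzene_plus_methyl_is_toluene(self, benzene):
        res = chemical_transform(benzene, seed=2, ops=("add",))
        assert res.graph.atom_count == 7
        assert to_smiles(res.graph) == Chem.CanonSmiles("Cc1ccccc1")

    def test_addition_products_stay_in_catalog(self, benzene):
        expected = {Chem.CanonSmiles(s) for s in
                    ("Cc1ccccc1", "Oc1ccccc1", "Fc1ccccc1",
                     "Clc1ccccc1", "Nc1ccccc1")}
        for seed in range(6):
            res = chemical_transform(benzene, seed=seed, ops=("add",))
            assert to_smiles(res.graph) in expected

    def test_methane_removal_only_infeasible(self):
        g = parse_smiles("C")
        with pytest.raises(AugmentationInfeasibleError):
            chemical_transform(g, seed=0, ops=("remove",))

    def test_deterministic(self, aspirin):
        r1 = chemical_transform(aspirin, seed=11)
        r2 = chemical_transform(aspirin, seed=11)
        assert to_smiles(r1.graph) == to_smiles(r2.graph)


class TestSubstructureRemove:
    def test_ethane_has_no_brics_bonds(self):
        with pytest.raises(AugmentationInfeasibleError):
            substructure_remove(parse_smiles("CC"), seed=0)

    def test_aspirin_fragment_is_valid_brics_cleavage(self, aspirin):
        res = substructure_remove(aspirin, seed=3)
        assert res.graph.atom_count < aspirin.atom_count
        validate_valence(res.graph)
        # reference oracle: enumerate every BRICS cleavage of aspirin and the
        # fragment retained after deleting the smaller side; result must match
        mol = to_rdkit(aspirin)
        expected = set()
        for (i, j), _ in BRICS.FindBRICSBonds(mol):
            em = Chem.RWMol(mol)
            Chem.Kekulize(em, clearAromaticFlags=True)
            em.RemoveBond(i, j)
            frags = Chem.GetMolFrags(em.GetMol())
            small = min(frags, key=len)
            em2 = Chem.RWMol(mol)
            Chem.Kekulize(em2, clearAromaticFlags=True)
            for idx in sorted(small, reverse=True):
                em2.RemoveAtom(idx)
            kept = em2.GetMol()
            Chem.SanitizeMol(kept)
            expected.add(Chem.MolToSmiles(kept))
        assert to_smiles(res.graph) in expected

    def test_deterministic(self, aspirin):
        r1 = substructure_remove(aspirin, seed=8)
        r2 = substructure_remove(aspirin, seed=8)
        assert to_smiles(r1.graph) == to_smiles(r2.graph)


class TestDissimilarity:
    def test_exact_copy_zero(self, aspirin):
        assert dissimilarity(aspirin, aspirin) == pytest.approx(0.0, abs=1e-6)

    def test_translated_copy_zero(self, aspirin):
        import dataclasses
        moved = dataclasses.replace(aspirin, coords=aspirin.coords + 4.2)
        assert dissimilarity(aspirin, moved) == pytest.approx(0.0, abs=1e-6)

    def test_rotation_invariant(self, aspirin):
        import dataclasses
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [1.0, 0.5, -0.7]).as_matrix()
        moved = dataclasses.replace(aspirin, coords=aspirin.coords @ R.T)
        assert dissimilarity(aspirin, moved) == pytest.approx(0.0, abs=1e-6)

    def test_no_common_substructure_infinite(self, benzene):
        methane = generate_conformer(parse_smiles("C"), seed=0)
        assert dissimilarity(benzene, methane) == float("inf")

    def test_missing_coords(self, aspirin):
        with pytest.raises(StateError):
            dissimilarity(aspirin, parse_smiles("CCO"))


class TestAcceptanceLoop:
    def test_accepted_below_threshold(self, aspirin):
        for seed in range(5):
            res = augment_accepted(aspirin, "node_drop", seed=seed)
            if res.accepted:
                assert res.dissimilarity < 3.0

    def test_infinite_threshold_first_candidate(self, aspirin):
        res = augment_accepted(aspirin, "subgraph", threshold=float("inf"), seed=1)
        assert res.accepted and res.attempts == 1

    def test_deterministic(self, aspirin):
        r1 = augment_accepted(aspirin, "chem_transform", seed=13)
        r2 = augment_accepted(aspirin, "chem_transform", seed=13)
        assert to_smiles(r1.graph) == to_smiles(r2.graph)
        assert r1.dissimilarity == r2.dissimilarity

    def test_invalid_arguments(self, aspirin):
        with pytest.raises(ValueError):
            augment_accepted(aspirin, "nonsense", seed=0)
        with pytest.raises(ValueError):
            augment_accepted(aspirin, "node_drop", threshold=-1.0, seed=0)


class TestBuildAugmentationSet:
    def test_four_members_all_valid(self, aspirin):
        aset = build_augmentation_set(aspirin, seed=3)
        assert set(aset.members) == set(KINDS)
        for res in aset.members.values():
            validate_valence(res.graph)
            assert res.graph.coords is not None

    def test_fallback_keeps_cardinality(self):
        # cyclohexane: no BRICS bonds, so substructure_removal must fall back
        g = generate_conformer(parse_smiles("C1CCCCC1"), seed=1)
        aset = build_augmentation_set(g, seed=2)
        assert set(aset.members) == set(KINDS)

    def test_deterministic(self, aspirin):
        a1 = build_augmentation_set(aspirin, seed=17)
        a2 = build_augmentation_set(aspirin, seed=17)
        for k in KINDS:
            assert to_smiles(a1.members[k].graph) == to_smiles(a2.members[k].graph)
            assert np.array_equal(a1.members[k].graph.coords,
                                  a2.members[k].graph.coords)
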