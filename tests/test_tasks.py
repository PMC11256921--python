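"""Retrieval metrics, property head, descriptor panel, editing harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moltext.errors import PromptError
from moltext.molgraph import parse_smiles
from moltext.tasks import (
    AffineCouplingFlow,
    DescriptorGenerator,
    EditConfig,
    IdentityTranslator,
    MLPTranslator,
    PropertyPanel,
    edit_optimize,
    editing_benchmark,
    hit_judge,
    prompt_anchor_embedding,
    property_panel,
    retrieval_eval,
    tanimoto_similarity,
    train_property_head,
)

rng = np.random.default_rng(0)


class TestRetrieval:
    def test_identity_pairing_perfect(self):
        E = rng.normal(size=(40, 16))
        rep = retrieval_eval(E, E, batch_size=8, n_batches=20, seed=1)
        assert rep.top1_accuracy == 1.0
        assert rep.recall_at_20 == 1.0

    def test_recall_nests_top1(self):
        M = rng.normal(size=(50, 8))
        T = rng.normal(size=(50, 8))
        rep = retrieval_eval(M, T, batch_size=30, n_batches=30, seed=2)
        assert rep.recall_at_20 >= rep.top1_accuracy

    def test_null_calibration_small(self):
        # independent random embeddings, drawn fresh per batch: top-1
        # concentrates at 1/batch_size
        bs, nb = 16, 200
        null = np.random.default_rng(3)
        hits = []
        for _ in range(nb):
            M = null.normal(size=(bs, 32))
            T = null.normal(size=(bs, 32))
            hits.append(retrieval_eval(M, T, batch_size=bs, n_batches=1,
                                       seed=0).top1_accuracy)
        p = 1.0 / bs
        se = np.sqrt(p * (1 - p) / (bs * nb))
        assert abs(np.mean(hits) - p) < 3 * se

    def test_batch_larger_than_corpus(self):
        E = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            retrieval_eval(E, E, batch_size=11, n_batches=1, seed=0)

    def test_pairing_must_be_bijection(self):
        E = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            retrieval_eval(E, E, pairing=np.zeros(10, dtype=int),
                           batch_size=5, n_batches=1, seed=0)

    def test_nonidentity_pairing_respected(self):
        E = rng.normal(size=(20, 8))
        perm = np.random.default_rng(5).permutation(20)
        T = np.empty_like(E)
        T[perm] = E          # text perm[i] equals molecule i
        rep = retrieval_eval(E, T, pairing=perm, batch_size=10,
                             n_batches=10, seed=6)
        assert rep.top1_accuracy == 1.0


class TestPropertyHead:
    def test_linearly_separable_perfect_auroc(self):
        X = rng.normal(size=(400, 16))
        w = rng.normal(size=16)
        margin = np.abs(X @ w) > 0.5      # separable with a margin
        X, score = X[margin][:200], (X @ w)[margin][:200]
        y = (score > 0).astype(int)
        res = train_property_head(X, y, seed=0)
        assert res.auroc == pytest.approx(1.0)

    def test_permuted_labels_near_chance(self):
        X = rng.normal(size=(200, 16))
        y = (X @ rng.normal(size=16) > 0).astype(int)
        y_perm = np.random.default_rng(7).permutation(y)
        res = train_property_head(X, y_perm, seed=0)
        assert 0.35 <= res.auroc <= 0.65

    def test_same_seed_same_result(self):
        X = rng.normal(size=(100, 8))
        y = rng.integers(0, 2, 100)
        assert train_property_head(X, y, seed=3).auroc == \
            train_property_head(X, y, seed=3).auroc

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_property_head(rng.normal(size=(20, 4)), np.ones(20), seed=0)


class TestPropertyPanel:
    def test_benzene_no_polar_atoms(self, benzene):
        p = property_panel(benzene)
        assert p.tpsa == 0.0 and p.hba == 0 and p.hbd == 0

    def test_methane(self):
        p = property_panel(parse_smiles("C"))
        assert p.hba == 0 and p.hbd == 0

    def test_aspirin_against_published_values(self, aspirin):
        # Ertl TPSA and Wildman-Crippen logP for acetylsalicylic acid
        p = property_panel(aspirin)
        assert p.tpsa == pytest.approx(63.60, abs=0.01)
        assert p.wclogp == pytest.approx(1.31, abs=0.01)
        assert p.hbd == 1
        assert 0.0 <= p.qed <= 1.0

    def test_invalid_panel_rejected(self):
        with pytest.raises(ValueError):
            PropertyPanel(tpsa=-1.0, hba=0, hbd=0, qed=0.5, wclogp=0.0)
        with pytest.raises(ValueError):
            PropertyPanel(tpsa=0.0, hba=0, hbd=0, qed=1.5, wclogp=0.0)


class TestHitJudge:
    BASE = PropertyPanel(tpsa=80.0, hba=4, hbd=2, qed=0.5, wclogp=1.0)

    @pytest.mark.parametrize("prompt,field,delta", [
        ("more_hba", "hba", +1), ("more_hbd", "hbd", +1),
        ("drug_like", "qed", +0.1), ("not_drug_like", "qed", -0.1),
        ("high_permeability", "tpsa", -20.0), ("low_permeability", "tpsa", +20.0),
        ("soluble", "wclogp", -0.5), ("insoluble", "wclogp", +0.5),
    ])
    def test_directions(self, prompt, field, delta):
        import dataclasses
        edited = dataclasses.replace(self.BASE,
                                     **{field: getattr(self.BASE, field) + delta})
        assert hit_judge(self.BASE, edited, prompt)
        assert not hit_judge(edited, self.BASE, prompt)

    def test_identical_panels_never_hit(self):
        for prompt in ("more_hba", "soluble", "drug_like", "high_permeability"):
            assert not hit_judge(self.BASE, self.BASE, prompt)

    def test_wrong_direction(self):
        import dataclasses
        edited = dataclasses.replace(self.BASE, wclogp=2.5)
        assert not hit_judge(self.BASE, edited, "soluble")

    def test_paired_prompt_antisymmetry(self):
        import dataclasses
        edited = dataclasses.replace(self.BASE, wclogp=0.2, tpsa=60.0, qed=0.7)
        for a, b in (("soluble", "insoluble"),
                     ("high_permeability", "low_permeability"),
                     ("drug_like", "not_drug_like")):
            if hit_judge(self.BASE, edited, a):
                assert hit_judge(edited, self.BASE, b)

    def test_unknown_prompt_lists_valid(self):
        with pytest.raises(PromptError, match="soluble"):
            hit_judge(self.BASE, self.BASE, "make_it_blue")


class TestTanimoto:
    def test_self_similarity_one(self, aspirin):
        assert tanimoto_similarity(aspirin, aspirin) == 1.0

    def test_symmetric(self, benzene, aspirin):
        assert tanimoto_similarity(benzene, aspirin) == \
            tanimoto_similarity(aspirin, benzene)

    def test_benzene_pyridine_frozen_reference(self, benzene):
        pyridine = parse_smiles("c1ccncc1")
        # value from the 2048-bit hashed path fingerprint reference
        assert tanimoto_similarity(benzene, pyridine) == \
            pytest.approx(0.2285714285714286, abs=1e-6)


class TestToyGenerator:
    @given(st.lists(st.floats(-3, 3), min_size=6, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_flow_invertible(self, xs):
        flow = AffineCouplingFlow(6, seed=1)
        x = np.asarray(xs)
        assert np.allclose(flow.inverse(flow.forward(x)), x, atol=1e-8)

    def test_decode_roundtrip_library_member(self, small_corpus):
        lib = [g for g, _ in small_corpus.pairs]
        gen = DescriptorGenerator(lib, seed=0)
        g0 = lib[3]
        assert gen.decode(gen.encode(g0)) is g0


class TestEditOptimize:
    def test_loss_strictly_reduced_identity_translator(self, small_corpus):
        lib = [g for g, _ in small_corpus.pairs]
        gen = DescriptorGenerator(lib, seed=0)
        zm = gen.encode(lib[0])
        cfg = EditConfig(steps=200, generator=gen, translator=IdentityTranslator())
        for seed in range(3):
            res = edit_optimize(zm, zm, cfg, seed=seed)
            assert res.loss_trace[-1] < res.loss_trace[0]
            assert all(np.isfinite(res.loss_trace))

    def test_zero_step_size_flat_trace(self):
        cfg = EditConfig(steps=10, step_size=0.0, latent_dim=6)
        res = edit_optimize(rng.normal(size=6), rng.normal(size=6), cfg, seed=0)
        assert res.loss_trace == pytest.approx([res.loss_trace[0]] * 11)

    def test_default_steps_600(self):
        assert EditConfig().steps == 600

    def test_mlp_translator_differentiable(self):
        tr = MLPTranslator(6, 16, seed=2)
        cfg = EditConfig(steps=50, translator=tr, latent_dim=6)
        res = edit_optimize(rng.normal(size=16), rng.normal(size=16), cfg, seed=1)
        assert res.loss_trace[-1] <= res.loss_trace[0]


class TestEditingBenchmark:
    @pytest.fixture
    def harness(self, small_corpus):
        lib = [g for g, _ in small_corpus.pairs]
        gen = DescriptorGenerator(lib, seed=0)
        tr = IdentityTranslator()
        return lib, gen, tr

    def test_forced_noop_zero_hits_full_similarity(self, harness):
        lib, gen, tr = harness
        cfg = EditConfig(steps=0, generator=gen, translator=tr,
                         init_from_molecule=True)
        anchor = prompt_anchor_embedding(gen, tr, "soluble")
        rep = editing_benchmark(lib, "soluble", cfg, seed=1,
                                text_embed=lambda _: anchor)
        assert rep.hit_ratio == 0.0
        assert rep.mean_similarity == pytest.approx(1.0)

    def test_bounds_and_real_edit_beats_noop(self, harness):
        lib, gen, tr = harness
        cfg = EditConfig(steps=100, generator=gen, translator=tr)
        anchor = prompt_anchor_embedding(gen, tr, "soluble")
        rep = editing_benchmark(lib, "soluble", cfg, seed=2,
                                text_embed=lambda _: anchor)
        assert 0.0 <= rep.hit_ratio <= 100.0
        assert 0.0 <= rep.mean_similarity <= 1.0
        assert rep.hit_ratio > 0.0

    def test_unknown_prompt(self, harness):
        lib, gen, tr = harness
        with pytest.raises(PromptError):
            editing_benchmark(lib, "nope", EditConfig(generator=gen), seed=0,
                              text_embed=lambda _: np.ones(6))
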