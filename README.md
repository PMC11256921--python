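# moltext

Joint 2D/3D molecule and text embeddings for cheminformatics, at desk scale.

Molecular property and similarity reasoning benefits from three modalities at
once: the 2D bond graph, the 3D conformer geometry, and the natural-language
knowledge written about compounds. `moltext` implements a multimodal embedding
framework for researchers who want a transparent, fully inspectable NumPy/RDKit
implementation of that idea: a graph-transformer molecule encoder whose
attention is biased by pairwise structural encodings, trained jointly with a
text encoder under contrastive objectives over RMSD-gated molecular
augmentations, plus evaluation harnesses for cross-modal retrieval, property
prediction and text-prompted molecule editing.

## The model

**Structure-biased attention.** For a molecule with *a* heavy atoms, three
scalar encodings are computed per atom pair (i, j):

- edge encoding  φᵢⱼᴱᵈᵍᵉ = avg(e)·w, the element-wise average of bond feature
  vectors along shortest i–j paths (averaged over all shortest paths), dotted
  with a learnable vector w ∈ ℝᵏ;
- distance encoding  φᵢⱼˢᴾᴰ = spd(i, j)·w, the bond-count shortest-path
  distance scaled by a learnable scalar;
- 3D encoding  φᵢⱼ³ᴰ = ReLU(ψ(i, j)·W₁)·w₂, a one-hidden-layer MLP over a
  K-vector of radial kernels ψₖ = exp(−‖xᵢ−xⱼ‖/σₖ) of the conformer
  interatomic distance (MMFF94-optimized geometry).

Their sum φ = φᴱᵈᵍᵉ + φˢᴾᴰ + φ³ᴰ is added to every attention layer's logits
before the softmax: softmax(QKᵀ/√d + φ)V. Atom states are mean-pooled and
projected into a 768-dimensional joint latent space shared with the text
encoder (a standard transformer over hashed tokens, truncated at 256 tokens).

**Contrastive pretraining.** Each molecule contributes four augmented views
(atom dropping, random-walk subgraph, functional-group transform, BRICS
fragment removal), each accepted only if its MCS-mapped, rigid-body-aligned
RMSD to the original is below 3.0 Å. For a batch of N molecules with views
z^{G1..G4} and caption embeddings z^{T1..T3}, training minimizes
L = L_cross + L_self, where L_cross is a temperature-scaled InfoNCE loss
−log[exp(sim(zᵢᴳᵃ, zᵢᵀ)/τ) / Σⱼ exp(sim(zᵢᴳᵃ, zⱼᵀ)/τ)] averaged over views,
caption variants and the batch, and L_self applies the analogous ratio to the
C(4,2) pairs of views of each molecule. Gradients flow through a small
reverse-mode autodiff engine included in the package.

## Worked example

`examples/03_pretrain_and_retrieve.py` builds a 32-pair toy corpus (captions
templated from computed descriptors so text genuinely correlates with
structure), pretrains the joint encoders, and evaluates retrieval:

```
$ python examples/03_pretrain_and_retrieve.py
epoch-mean total loss: first 3.789 -> final 2.404
molecule->text retrieval: top-1 0.205 (chance 0.125), R@20 1.000
```

The loss drop shows the contrastive objective is being optimized; top-1 of
0.205 in batches of 8 versus the 0.125 chance rate shows molecule and caption
embeddings have aligned after ~30 epochs on one CPU. The other examples cover
featurization (`01`), augmentation (`02`), latent-space editing against a
descriptor prompt (`04`) and a linear property-prediction head (`05`).

A thin CLI mirrors the same capabilities
(`moltext featurize|augment|pretrain|retrieve|edit|fixtures`); run
`moltext --help` for usage.

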