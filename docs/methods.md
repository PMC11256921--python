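# Methods

This note records the model, its assumptions, the parameter choices that
matter, and the design decisions taken where the design was genuinely open.

## Molecular graphs

Graphs are heavy-atom graphs: hydrogens are implicit throughout (they are
added temporarily for 3D embedding and stripped afterwards). Atoms are
0-based indexed; undirected bonds are stored once. Each bond carries a
6-slot binary feature vector: one-hot bond order (single/double/triple/
aromatic), an in-ring flag and a conjugation flag. Stereochemistry flags are
a possible extension slot but are not part of the default schema.

Conformers come from distance-geometry embedding (ETKDGv3) followed by
MMFF94 minimization, seeded and bounded to 10 embedding attempts; identical
(molecule, seed) inputs give bitwise-identical coordinates. Coordinates are
in Ångström.

Shortest-path distances are unweighted bond counts. Disconnected pairs carry
the sentinel value *a* (the atom count): finite, order-preserving, and larger
than any realizable path, so the encoder needs no special code path for
fragments. `shortest_path_edge_features` resolves ties among equal-length
paths deterministically: the breadth-first path from the smaller endpoint,
expanding neighbors in ascending index order, making the result symmetric in
(i, j).

## Structural encodings and the attention bias

Three pairwise scalar encodings are linearly combined into one symmetric
a×a bias matrix added to the pre-softmax attention logits of every molecule
encoder layer (one shared matrix across heads; per-head scaling would be a
config extension):

- **Edge encoding.** The element-wise average of bond feature vectors along
  shortest i–j paths, dotted with a learnable k_edge-vector. Where several
  shortest paths exist, the average is taken uniformly over *all* of them
  (a dynamic program over the shortest-path DAG). This choice is deliberate:
  a single index-tie-broken path is not invariant under atom renumbering
  (two equal-length ring paths can carry different bond features), and
  permutation invariance of the final embedding is a property we consider
  non-negotiable for a graph encoder. The path-query API keeps the
  deterministic single-path semantics; only the encoding averages over paths.
  Unreachable pairs and the diagonal contribute 0.
- **SPD encoding.** The shortest-path distance (sentinel included) times a
  learnable scalar.
- **3D encoding.** ψ(i,j) is a K-vector of radial kernels of the Euclidean
  interatomic distance; the encoding is ReLU(ψ·W₁)·w₂ with learnable W₁
  (K×K) and w₂ (K). The default kernel is the exponential decay
  exp(−d/σₖ) — the literal reading of the defining formula — with a Gaussian
  bump form exp(−(d−μₖ)²/2σₖ²) over an even grid of centers available via
  `kernel_form="gaussian"`, since the family is conventionally Gaussian.
  σₖ defaults to a geometric grid from 0.5 Å to 10 Å over K = 8 kernels,
  spanning bonded contacts through long intramolecular distances for
  drug-sized molecules. The diagonal is evaluated at d = 0 (not zeroed),
  since the formula is defined for all pairs.

The 3D term depends only on pairwise distances, so it is exactly invariant
under rigid-body motion; all three terms commute with atom renumbering.

## Encoders

Molecule encoder: per-atom inputs are summed learned embeddings of element
(13-symbol vocabulary plus a catch-all), heavy-atom degree (0–6) and formal
charge (clipped to ±2); the stack is a pre-layer-norm
transformer (attention + 2×-wide ReLU feed-forward, residual connections)
with the structural bias added to each layer's logits. Atom states are
mean-pooled and linearly projected to the joint width. Desk-scale defaults:
2 layers, 4 heads, model width 64, joint width 768 (the width standard for
BERT-family text encoders, kept so external decoders and heads expecting
768-dimensional inputs plug in unchanged). Everything is configurable.

Text encoder: whitespace/punctuation tokens hashed (CRC-32) into a 512-slot
vocabulary, learned token + position embeddings, the same transformer stack
without bias, mean-pooling, projection to the joint width. Inputs are
truncated at 256 tokens. The encoder is weight-agnostic — any compatible
parameter set can be loaded in place of the random initialization (e.g.
weights converted from a pretrained biomedical text model); the package
ships no checkpoint.

Embeddings are L2-normalized exactly once, inside the similarity/loss
computations, never inside the encoders.

Because no installed library provides reverse-mode differentiation, the
package includes a compact autodiff engine over NumPy arrays
(`moltext.autodiff`) supporting the operations the encoders and losses use.
Its gradients are pinned against central finite differences in the test
suite (worst relative error ~1e-7 at ε = 1e-6).

## Augmentations and the RMSD gate

Four kinds, all operating on the sanitized RDKit molecule and re-embedded in
3D afterwards:

- **node_drop** removes ⌈0.1·a⌉ atoms uniformly (10% is deliberately
  conservative since the original molecule itself is never a training view),
  resampling up to 20 times until the remainder is connected and sanitizes.
- **subgraph** keeps the induced subgraph on atoms visited by a seeded
  random walk (target 80% of atoms, at most 10·a steps). The 80% default
  keeps the view informative while still distinct; the walk guarantees
  connectivity by construction.
- **chem_transform** adds or removes one functional group from a fixed
  five-group catalog (methyl, hydroxyl, fluoro, chloro, amino) at a
  uniformly chosen legal site (free valence for additions; terminal matching
  atoms for removals).
- **substructure_removal** cleaves one BRICS bond, chosen uniformly among
  those whose retained (larger) fragment keeps ≥ 3 atoms, and discards the
  smaller fragment; open valences are capped with implicit hydrogens.

Dissimilarity between original and variant is the coordinate RMSD (Å) after
a maximum-common-substructure atom mapping (≥ 3 mapped atoms required, else
+∞) and optimal rigid superposition over the mapped atoms. A candidate is
accepted below 3.0 Å; the acceptance loop retries with fresh sub-seeds up to
10 times and otherwise returns the least-dissimilar candidate flagged
unaccepted. Chemistry kinds that are infeasible for a molecule (no BRICS
bonds, no legal group move) fall back to node_drop under a distinct
sub-seed, so every molecule always yields exactly four views.

## Contrastive objective

With four graph views and up to three caption embeddings per molecule in a
batch of N:

- **Cross-modal loss**: for every (view a, caption variant t),
  −log[exp(sim(zᵢᴳᵃ, zᵢᵀᵗ)/τ) / Σⱼ exp(sim(zᵢᴳᵃ, zⱼᵀᵗ)/τ)], averaged over
  the 4×3 combinations and the batch. The aggregation over views/variants is
  a design choice (the defining equation writes a single pair); averaging
  uses all views without bias. The denominator runs over texts
  (molecule→text direction) by default; a symmetric both-direction variant
  sits behind `direction="symmetric"`. Items with fewer than three captions
  have their variants cycled.
- **Self-contrastive loss**: with pair kernel k(i, j) summing
  exp(sim(zᵢᴳᵃ, zⱼᴳᵇ)/τ) over the C(4,2) unordered view pairs — averaged
  over the two orientations so the kernel is indifferent to how the view
  slots are ordered — the loss is −log[k(i,i)/Σⱼ k(i,j)], batch-averaged.

Both losses are exactly 0 at N = 1 and equal ln N under constant
similarities; these limits are asserted in the tests. τ is fixed (not
learned) at 0.1, a standard temperature for normalized-embedding InfoNCE.

Training is plain SGD with momentum 0.9, learning rate 1e-3, batch size 8,
30 epochs at desk scale. Augmentation sets and caption tokenizations are
precomputed once per run; shuffling, augmentation and initialization all
derive from one seed, so traces reproduce bitwise. At these sizes a full run
(32 molecules) takes ~25 s on one CPU.

## Synthetic corpus

The generator samples from ~45 built-in drug-like SMILES (aspirin, caffeine,
amino acids, simple aromatics …) chosen for fast conformer generation and
diverse functional groups; requests beyond the list are filled with seeded
functional-group variants. Each molecule gets three caption variants
templated from its computed descriptor panel (H-bond acceptor/donor counts,
TPSA, Crippen logP, QED, formula), so captions correlate with structure by
construction. What this does *not* emulate: the linguistic variety, noise
and weak pairing of literature-mined text, vocabulary beyond the templates,
and corpus scale. Passing tests therefore demonstrate that the machinery
optimizes and aligns modalities under clean conditions, not that the learned
embeddings transfer to real biomedical text.

## Downstream harnesses

- **Retrieval**: seeded batches (default 64) of paired embeddings; a query's
  candidates are its batch's opposite modality ranked by cosine; top-1 and
  R@20 are averaged over batches. Under the null (independent random
  embeddings drawn fresh per batch) top-1 concentrates at 1/batch-size;
  with a small *fixed* corpus re-sampled into batches, per-pair luck
  correlates across batches and inflates the variance — the calibration
  check therefore uses fresh draws.
- **Property head**: logistic regression (C = 100, weak regularization so
  separable data can be ranked perfectly) on an 80/20 stratified seeded
  split; held-out AUROC.
- **Editing**: gradient descent on a latent of an invertible generator;
  the candidate joint-space embedding c = translator(latent) is pulled
  toward the original molecule's embedding and a prompt anchor:
  loss = (1 − cos(c, z_mol)) + λ(1 − cos(c, z_text)), λ = 1, 600 steps,
  with the step size halved whenever a step would increase the loss (hence
  a monotone trace). The prompt-alignment term acts on the *candidate*
  embedding: aligning two fixed embeddings would carry no gradient. The
  shipped generator is a toy exactly-invertible affine-coupling flow over a
  standardized 6-descriptor vector (TPSA, HBA, HBD, QED, logP, heavy-atom
  count) that decodes to the nearest library molecule in descriptor space —
  it exercises the full optimization/decode/judge loop at desk scale but
  does not generate novel structures. Hit rules are strict inequalities on
  the descriptor each prompt names (e.g. "soluble" requires logP to
  decrease), with zero margin.
- **Prompt anchors**: the toy harness builds a prompt's text embedding as
  the mean translated latent of the library molecules that best exemplify
  the prompted direction, giving the optimizer a real signal in descriptor
  space.

## Numerical choices and degenerate inputs

- Softmax/logsumexp are max-shifted; gradients accumulate in float64.
- Cosine similarity rejects zero vectors; embeddings are validated finite.
- Single-atom molecules: 1×1 zero bias, valid embedding; empty text is
  rejected.
- The RMSD of a molecule against an exact copy evaluates to ~1e-8 (alignment
  round-off), not exactly 0; tests use 1e-6 tolerances for such checks.
- MCS search is capped at 10 s per pair (never reached at desk scale).

## Known limitations

Desk scale only: random-initialized text weights, a 45-molecule corpus pool
and a descriptor-space generator mean absolute downstream numbers are not
comparable to GPU-scale results on mined corpora; the package's claims are
the structural and statistical properties its tests assert. BRICS-free
molecules exercise the fallback path rather than true substructure removal.
The tokenizer's hashed vocabulary admits collisions by design.
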