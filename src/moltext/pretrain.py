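"""Contrastive objectives and the seeded molecule-text pretraining loop.

Two temperature-scaled InfoNCE-style losses supervise the joint space.
For a mini-batch of N molecules, each contributing four augmented graph
embeddings z^{G1..G4} and up to three text embeddings z^{T1..T3}:

* the cross-modal loss pulls each graph view toward its own texts:
  for every (view a, variant t) pair,
  -log[ exp(sim(z_i^Ga, z_i^Tt)/tau) / sum_j exp(sim(z_i^Ga, z_j^Tt)/tau) ],
  averaged over views, variants and the batch;
* the self-contrastive loss pulls the four views of one molecule together:
  with pair kernel k(i, j) = sum over the C(4,2) unordered view pairs {a, b}
  of exp(sim(z_i^Ga, z_j^Gb)/tau), averaged over the two orientations so the
  kernel is indifferent to how the view slots are ordered, the loss is
  -log[ k(i, i) / sum_j k(i, j) ], averaged over the batch.

Both losses are exactly 0 for N = 1 and equal ln N under constant
similarities. Embeddings are L2-normalized inside the loss (cosine
similarity), never inside the encoders. The total objective is their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .augment import build_augmentation_set
from .encoders import (
    EncoderConfig,
    ModelWeights,
    encode_molecule_t,
    encode_text_t,
    graph_features,
    tokenize,
)


@dataclass
class LossConfig:
    tau: float = 0.1
    text_variants: int = 3
    direction: str = "as_printed"   # molecule->text only; or "symmetric"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")
        if self.text_variants < 1:
            raise ValueError("text_variants must be >= 1")
        if self.direction not in ("as_printed", "symmetric"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class BatchItem:
    graph_embs: list          # four embedding vectors (np arrays or Tensors)
    text_embs: list           # 1..3 embedding vectors


@dataclass
class Batch:
    items: list

    def __post_init__(self):
        if len(self.items) < 1:
            raise ValueError("batch must contain at least one item")


def _stack_batch(batch: Batch, need_text: bool, variants: int):
    """(N, 4, D) graph tensor and (N, V, D) text tensor (variants cycled)."""
    gs, ts = [], []
    for item in batch.items:
        if len(item.graph_embs) != 4:
            raise ValueError(
                f"each item needs exactly 4 graph views, got {len(item.graph_embs)}")
        gs.append(ad.stack([Tensor._wrap(g) for g in item.graph_embs]))
        if need_text:
            if len(item.text_embs) < 1:
                raise ValueError("each item needs at least one text embedding")
            cyc = [Tensor._wrap(item.text_embs[t % len(item.text_embs)])
                   for t in range(variants)]
            ts.append(ad.stack(cyc))
    G = ad.stack(gs)
    T = ad.stack(ts) if need_text else None
    return G, T


def cross_modal_loss_t(G: Tensor, T: Tensor, config: LossConfig) -> Tensor:
    """Cross-modal InfoNCE on stacked tensors G (N,4,D), T (N,V,D)."""
    N = G.shape[0]
    Gn = ad.l2_normalize(G)
    Tn = ad.l2_normalize(T)
    n_aug, n_var = G.shape[1], T.shape[1]
    idx = np.arange(N)
    terms = []
    for a in range(n_aug):
        Ga = Gn[:, a, :]
        for t in range(n_var):
            Tt = Tn[:, t, :]
            S = (Ga @ Tt.T) / config.tau           # (N, N)
            diag = S[idx, idx]
            terms.append((ad.logsumexp(S, axis=1) - diag).mean())
            if config.direction == "symmetric":
                terms.append((ad.logsumexp(S.T, axis=1) - diag).mean())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / float(len(terms))


def self_contrastive_loss_t(G: Tensor, config: LossConfig) -> Tensor:
    """Self-contrastive loss over the four augmented views, G (N,4,D)."""
    N = G.shape[0]
    Gn = ad.l2_normalize(G)
    pair_sum = None
    for a in range(4):
        for b in range(a + 1, 4):
            S = ((Gn[:, a, :] @ Gn[:, b, :].T) / config.tau).exp()   # (N, N)
            pair_sum = S if pair_sum is None else pair_sum + S
    # average the two view orientations so the kernel does not depend on how
    # the four augmentation slots are ordered
    pair_sum = (pair_sum + pair_sum.T) * 0.5
    idx = np.arange(N)
    num = pair_sum[idx, idx]
    den = pair_sum.sum(axis=1)
    return -((num / den).log()).mean()


def cross_modal_loss(batch: Batch, config: LossConfig | None = None) -> float:
    config = config or LossConfig()
    G, T = _stack_batch(batch, need_text=True, variants=config.text_variants)
    _check_nonzero(G), _check_nonzero(T)
    return float(cross_modal_loss_t(G, T, config).data)


def self_contrastive_loss(batch: Batch, config: LossConfig | None = None) -> float:
    config = config or LossConfig()
    G, _ = _stack_batch(batch, need_text=False, variants=1)
    _check_nonzero(G)
    return float(self_contrastive_loss_t(G, config).data)


def total_loss(batch: Batch, config: LossConfig | None = None) -> float:
    """L = L_cross + L_self."""
    return cross_modal_loss(batch, config) + self_contrastive_loss(batch, config)


def _check_nonzero(T: Tensor) -> None:
    norms = np.linalg.norm(T.data, axis=-1)
    if np.any(norms == 0):
        raise ValueError("zero embedding in batch; similarity undefined")


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    loss: LossConfig = field(default_factory=LossConfig)
    epochs: int = 30
    batch_size: int = 8
    lr: float = 1e-3
    momentum: float = 0.9
    mode: str = "3D"
    augment_threshold: float = 3.0
    augment_tries: int = 10


@dataclass
class TrainResult:
    weights: ModelWeights
    epoch_losses: list
    batch_losses: list


def prepare_corpus(pairs, config: EncoderConfig, sigmas, seed: int,
                   mode: str = "3D", threshold: float = 3.0,
                   max_tries: int = 10) -> list:
    """Augment every molecule once and precompute encoder inputs.

    ``pairs`` is a list of (MolecularGraph, [caption, ...]). Returns a list of
    (list-of-4 GraphFeatures, list of token-id arrays) ready for the loop.
    The original molecule itself is never encoded during training; only the
    four augmented views are.
    """
    prepared = []
    for i, (graph, captions) in enumerate(pairs):
        aug = build_augmentation_set(graph, seed=(seed * 7919 + i) % 2**31,
                                     threshold=threshold, max_tries=max_tries)
        feats = [graph_features(g, config, sigmas, mode) for g in aug.graphs()]
        ids = [tokenize(c, config.vocab_size, config.max_tokens)
               for c in captions if c.strip()]
        if not ids:
            raise ValueError(f"molecule {i} has no usable captions")
        prepared.append((feats, ids))
    return prepared


def train(corpus, weights: ModelWeights, config: TrainConfig | None = None,
          seed: int = 0) -> TrainResult:
    """Seeded SGD-with-momentum pretraining over molecule-text pairs.

    ``corpus`` is a list of (MolecularGraph, [captions]) pairs (e.g.
    ``ToyCorpus.pairs``). Augmentation sets are generated once up front;
    identical seeds reproduce identical loss traces.
    """
    config = config or TrainConfig()
    if not corpus:
        raise ValueError("corpus is empty")
    if config.batch_size > len(corpus):
        raise ValueError("batch size exceeds corpus size")
    prepared = prepare_corpus(corpus, weights.config, weights.sigmas, seed,
                              config.mode, config.augment_threshold,
                              config.augment_tries)
    rng = np.random.default_rng(seed)
    velocity = {k: np.zeros_like(t.data) for k, t in weights.trainable()}
    epoch_losses, batch_losses = [], []
    for epoch in range(config.epochs):
        order = rng.permutation(len(prepared))
        epoch_vals = []
        for start in range(0, len(order) - 1, config.batch_size):
            idxs = order[start:start + config.batch_size]
            if len(idxs) < 2:
                continue
            items = []
            for i in idxs:
                feats, ids = prepared[i]
                g_embs = [encode_molecule_t(f, weights, config.mode) for f in feats]
                t_embs = [encode_text_t(tid, weights) for tid in ids]
                items.append(BatchItem(g_embs, t_embs))
            G, T = _stack_batch(Batch(items), True, config.loss.text_variants)
            loss = cross_modal_loss_t(G, T, config.loss) \
                + self_contrastive_loss_t(G, config.loss)
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}")
            weights.zero_grad()
            loss.backward()
            for k, t in weights.trainable():
                g = t.grad if t.grad is not None else np.zeros_like(t.data)
                velocity[k] = config.momentum * velocity[k] - config.lr * g
                t.data = t.data + velocity[k]
            epoch_vals.append(val)
            batch_losses.append(val)
        epoch_losses.append(float(np.mean(epoch_vals)))
    return TrainResult(weights, epoch_losses, batch_losses)
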