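"""Molecule and text transformer encoders producing joint-space embeddings.

The molecule encoder is a graph transformer: per-atom input features are
summed learned embeddings of (element, degree, formal charge); every
attention layer adds the combined 2D/3D structural bias matrix to its
pre-softmax logits (one shared bias across heads). Atom states are
mean-pooled and linearly projected to the joint embedding width (default
768). Because every ingredient — atom features, path-averaged edge
encodings, shortest-path distances, interatomic-distance kernels, attention
and mean pooling — commutes with atom renumbering, the pooled embedding is
permutation-invariant.

The text encoder is a standard (bias-free) transformer over hashed word
tokens with learned positions, truncated at ``max_tokens`` (default 256),
mean-pooled and projected to the same joint space. It is weight-agnostic:
any compatible parameter set can be supplied (e.g. converted pretrained
weights); the desk-scale default is a small randomly initialized encoder.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoding import EncodingParams, _kernel, default_sigmas, distance_matrix
from .errors import ConfigError, StateError
from .molgraph import MolecularGraph, path_averaged_edge_features, spd_matrix

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se", "*")
MAX_DEGREE = 6
CHARGE_RANGE = (-2, 2)


@dataclass
class EncoderConfig:
    layers: int = 2
    heads: int = 4
    model_dim: int = 64
    embed_dim: int = 768
    max_tokens: int = 256
    vocab_size: int = 512
    k_edge: int = 6
    K: int = 8                      # number of radial distance kernels
    kernel_form: str = "decay"

    def __post_init__(self):
        if self.model_dim % self.heads != 0:
            raise ConfigError("model_dim must be divisible by heads")
        if self.embed_dim <= 0 or self.max_tokens <= 0:
            raise ConfigError("embed_dim and max_tokens must be positive")


@dataclass
class Embedding:
    """A vector in the joint molecule-text latent space."""

    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding has non-finite entries")
        self.vector = v

    def normalized(self) -> np.ndarray:
        n = np.linalg.norm(self.vector)
        if n == 0:
            raise ValueError("cannot normalize a zero embedding")
        return self.vector / n


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass
class ModelWeights:
    """All learnable parameters (autodiff tensors) plus kernel metadata."""

    config: EncoderConfig
    params: dict
    sigmas: np.ndarray = field(default_factory=default_sigmas)

    @classmethod
    def init(cls, config: EncoderConfig, seed: int) -> "ModelWeights":
        rng = np.random.default_rng(seed)

        def mat(fan_in, *shape):
            return Tensor(rng.normal(0, 1.0 / np.sqrt(fan_in), shape),
                          requires_grad=True)

        def emb(n, d, scale=0.1):
            return Tensor(rng.normal(0, scale, (n, d)), requires_grad=True)

        dm, ed = config.model_dim, config.embed_dim
        p: dict = {}
        # encoding weights (shared by every molecule-encoder layer)
        p["enc.w_edge"] = Tensor(rng.normal(0, 0.05, config.k_edge),
                                 requires_grad=True)
        p["enc.w_spd"] = Tensor(rng.normal(0, 0.05), requires_grad=True)
        p["enc.W1"] = mat(config.K, config.K, config.K)
        p["enc.w2"] = Tensor(rng.normal(0, 0.05, config.K), requires_grad=True)
        # molecule branch
        p["mol.elem"] = emb(len(ELEMENTS), dm)
        p["mol.deg"] = emb(MAX_DEGREE + 1, dm)
        p["mol.chg"] = emb(CHARGE_RANGE[1] - CHARGE_RANGE[0] + 1, dm)
        for side, nl in (("mol", config.layers), ("txt", config.layers)):
            for l in range(nl):
                pre = f"{side}.{l}."
                for name in ("Wq", "Wk", "Wv", "Wo"):
                    p[pre + name] = mat(dm, dm, dm)
                p[pre + "ln1_g"] = Tensor(np.ones(dm), requires_grad=True)
                p[pre + "ln1_b"] = Tensor(np.zeros(dm), requires_grad=True)
                p[pre + "ln2_g"] = Tensor(np.ones(dm), requires_grad=True)
                p[pre + "ln2_b"] = Tensor(np.zeros(dm), requires_grad=True)
                p[pre + "F1"] = mat(dm, dm, 2 * dm)
                p[pre + "f1"] = Tensor(np.zeros(2 * dm), requires_grad=True)
                p[pre + "F2"] = mat(2 * dm, 2 * dm, dm)
                p[pre + "f2"] = Tensor(np.zeros(dm), requires_grad=True)
            p[f"{side}.proj"] = mat(dm, dm, ed)
            p[f"{side}.proj_b"] = Tensor(np.zeros(ed), requires_grad=True)
        # text branch inputs
        p["txt.tok"] = emb(config.vocab_size, dm)
        p["txt.pos"] = emb(config.max_tokens, dm)
        return cls(config=config, params=p, sigmas=default_sigmas(config.K))

    def encoding_params(self) -> EncodingParams:
        """Numpy view of the current structural-encoding weights."""
        return EncodingParams(
            w_edge=self.params["enc.w_edge"].data.copy(),
            w_spd=float(self.params["enc.w_spd"].data),
            sigmas=self.sigmas.copy(),
            W1=self.params["enc.W1"].data.copy(),
            w2=self.params["enc.w2"].data.copy(),
            kernel_form=self.config.kernel_form,
        )

    def trainable(self):
        return [(k, t) for k, t in self.params.items() if t.requires_grad]

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

@dataclass
class GraphFeatures:
    """Weight-independent per-graph arrays consumed by the encoder."""

    elem_idx: np.ndarray
    deg_idx: np.ndarray
    chg_idx: np.ndarray
    avg_edge: np.ndarray      # (a, a, k_edge)
    spd: np.ndarray           # (a, a) float, sentinel a for unreachable
    psi: np.ndarray | None    # (a, a, K) radial kernel responses, 3D only


def graph_features(graph: MolecularGraph, config: EncoderConfig,
                   sigmas: np.ndarray, mode: str = "2D") -> GraphFeatures:
    elem_idx = np.array(
        [ELEMENTS.index(a.element) if a.element in ELEMENTS else len(ELEMENTS) - 1
         for a in graph.atoms], dtype=int)
    deg_idx = np.array([min(a.degree, MAX_DEGREE) for a in graph.atoms], dtype=int)
    chg_idx = np.array(
        [np.clip(a.formal_charge, *CHARGE_RANGE) - CHARGE_RANGE[0]
         for a in graph.atoms], dtype=int)
    avg_edge = path_averaged_edge_features(graph)
    if avg_edge.shape[-1] != config.k_edge:
        raise ConfigError(
            f"graph k_edge {avg_edge.shape[-1]} != config k_edge {config.k_edge}")
    spd = spd_matrix(graph).astype(float)
    psi = None
    if mode == "3D":
        if graph.coords is None:
            raise StateError("3D mode needs coordinates; run generate_conformer")
        ep = EncodingParams(w_edge=np.zeros(config.k_edge), sigmas=sigmas,
                            kernel_form=config.kernel_form)
        psi = _kernel(distance_matrix(graph), ep)
    return GraphFeatures(elem_idx, deg_idx, chg_idx, avg_edge, spd, psi)


# ---------------------------------------------------------------------------
# Transformer internals (autodiff path)
# ---------------------------------------------------------------------------

def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * g + b


def _attention(x: Tensor, w: ModelWeights, pre: str, bias: Tensor | None) -> Tensor:
    cfg = w.config
    a = x.shape[0]
    H, dh = cfg.heads, cfg.model_dim // cfg.heads
    p = w.params

    def split(t):  # (a, dm) -> (H, a, dh)
        return t.reshape(a, H, dh).transpose(1, 0, 2)

    q = split(x @ p[pre + "Wq"])
    k = split(x @ p[pre + "Wk"])
    v = split(x @ p[pre + "Wv"])
    logits = (q @ k.transpose(0, 2, 1)) / np.sqrt(dh)
    if bias is not None:
        logits = logits + bias        # (H,a,a) + (a,a) broadcast
    att = ad.softmax(logits, axis=-1)
    out = (att @ v).transpose(1, 0, 2).reshape(a, cfg.model_dim)
    return out @ p[pre + "Wo"]


def _encoder_stack(x: Tensor, w: ModelWeights, side: str,
                   bias: Tensor | None) -> Tensor:
    p = w.params
    for l in range(w.config.layers):
        pre = f"{side}.{l}."
        x = x + _attention(_layer_norm(x, p[pre + "ln1_g"], p[pre + "ln1_b"]),
                           w, pre, bias)
        h = _layer_norm(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
        x = x + (h @ p[pre + "F1"] + p[pre + "f1"]).relu() @ p[pre + "F2"] + p[pre + "f2"]
    pooled = x.mean(axis=0)
    return pooled @ p[f"{side}.proj"] + p[f"{side}.proj_b"]


def bias_tensor(feats: GraphFeatures, w: ModelWeights, mode: str) -> Tensor:
    """Combined structural bias as an autodiff tensor (a, a)."""
    a = feats.spd.shape[0]
    k = feats.avg_edge.shape[-1]
    p = w.params
    edge = (Tensor(feats.avg_edge.reshape(a * a, k)) @ p["enc.w_edge"]).reshape(a, a)
    spd = Tensor(feats.spd) * p["enc.w_spd"]
    total = edge + spd
    if mode == "3D":
        K = feats.psi.shape[-1]
        hid = (Tensor(feats.psi.reshape(a * a, K)) @ p["enc.W1"]).relu()
        total = total + (hid @ p["enc.w2"]).reshape(a, a)
    return total


def encode_molecule_t(feats: GraphFeatures, w: ModelWeights, mode: str) -> Tensor:
    p = w.params
    x = p["mol.elem"][feats.elem_idx] + p["mol.deg"][feats.deg_idx] \
        + p["mol.chg"][feats.chg_idx]
    return _encoder_stack(x, w, "mol", bias_tensor(feats, w, mode))


_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str, vocab_size: int, max_tokens: int) -> np.ndarray:
    """Hash word/punctuation tokens into a fixed vocabulary, then truncate."""
    toks = _TOKEN_RE.findall(text.lower())
    ids = [zlib.crc32(t.encode("utf-8")) % vocab_size for t in toks]
    return np.array(ids[:max_tokens], dtype=int)


def encode_text_t(ids: np.ndarray, w: ModelWeights) -> Tensor:
    p = w.params
    x = p["txt.tok"][ids] + p["txt.pos"][np.arange(len(ids))]
    return _encoder_stack(x, w, "txt", None)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def biased_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                     bias) -> np.ndarray:
    """softmax(Q K^T / sqrt(d) + bias) V for plain 2-D arrays."""
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    B = np.asarray(getattr(bias, "values", bias), dtype=float)
    a = Q.shape[0]
    if K.shape[0] != a or V.shape[0] != a or B.shape != (a, a):
        raise ValueError(
            f"shape mismatch: Q{Q.shape} K{K.shape} V{V.shape} bias{B.shape}")
    logits = Q @ K.T / np.sqrt(Q.shape[1]) + B
    logits -= logits.max(axis=1, keepdims=True)
    att = np.exp(logits)
    att /= att.sum(axis=1, keepdims=True)
    return att @ V


def encode_molecule(graph: MolecularGraph, weights: ModelWeights,
                    config: EncoderConfig | None = None,
                    mode: str = "2D") -> Embedding:
    """Deterministic joint-space embedding of a molecular graph."""
    cfg = config or weights.config
    feats = graph_features(graph, cfg, weights.sigmas, mode)
    return Embedding(encode_molecule_t(feats, weights, mode).data)


def encode_text(text: str, weights: ModelWeights,
                config: EncoderConfig | None = None) -> Embedding:
    cfg = config or weights.config
    if not text or not text.strip():
        raise ValueError("cannot encode empty text")
    ids = tokenize(text, cfg.vocab_size, cfg.max_tokens)
    return Embedding(encode_text_t(ids, weights).data)


def cosine_similarity(z1, z2) -> float:
    """Cosine similarity in [-1, 1]; raises on zero vectors."""
    v1 = z1.vector if isinstance(z1, Embedding) else np.asarray(z1, dtype=float)
    v2 = z2.vector if isinstance(z2, Embedding) else np.asarray(z2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
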