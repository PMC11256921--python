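"""Pairwise 2D/3D structural encodings and the combined attention-bias matrix.

Three scalar pairwise encodings are computed per atom pair (i, j):

* edge encoding    phi_ij^Edge = avg(e) . w_edge, the element-wise average of
  bond feature vectors along shortest i-j paths dotted with a learnable vector;
* SPD encoding     phi_ij^SPD  = spd(i, j) * w_spd, the bond-count shortest
  path distance scaled by a learnable scalar;
* 3D encoding      phi_ij^3D   = ReLU(psi(i, j) @ W1) . w2, a one-hidden-layer
  MLP over a K-vector of radial kernels of the Euclidean distance |x_i - x_j|.

Their sum is added, pre-softmax, to the attention logits of every molecule
transformer layer. The default radial kernel is the exponential decay
exp(-d / sigma_k); a Gaussian bump form exp(-(d - mu_k)^2 / (2 sigma_k^2))
over an even grid of centers is available via ``kernel_form="gaussian"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, StateError
from .molgraph import MolecularGraph, path_averaged_edge_features, spd_matrix


def default_sigmas(K: int = 8, lo: float = 0.5, hi: float = 10.0) -> np.ndarray:
    """Geometric grid of kernel widths (Angstrom) from lo to hi."""
    return np.geomspace(lo, hi, K)


@dataclass
class EncodingParams:
    """Learnable weights and kernel hyperparameters of the bias encodings."""

    w_edge: np.ndarray = field(default_factory=lambda: np.zeros(6))
    w_spd: float = 0.0
    sigmas: np.ndarray = field(default_factory=default_sigmas)
    W1: np.ndarray | None = None
    w2: np.ndarray | None = None
    kernel_form: str = "decay"  # "decay" | "gaussian"
    d_max: float = 10.0         # grid upper end for gaussian centers

    def __post_init__(self):
        self.w_edge = np.asarray(self.w_edge, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if np.any(self.sigmas <= 0):
            raise ConfigError("all kernel widths sigma_k must be positive")
        K = self.K
        if self.W1 is None:
            self.W1 = np.eye(K)
        if self.w2 is None:
            self.w2 = np.zeros(K)
        self.W1 = np.asarray(self.W1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.W1.shape != (K, K):
            raise ConfigError(f"W1 must be ({K}, {K}), got {self.W1.shape}")
        if self.w2.shape != (K,):
            raise ConfigError(f"w2 must be length {K}, got {self.w2.shape}")
        if self.kernel_form not in ("decay", "gaussian"):
            raise ConfigError(f"unknown kernel_form: {self.kernel_form!r}")

    @property
    def K(self) -> int:
        return len(self.sigmas)

    @classmethod
    def random(cls, seed: int, k_edge: int = 6, K: int = 8,
               scale: float = 0.1, kernel_form: str = "decay") -> "EncodingParams":
        rng = np.random.default_rng(seed)
        return cls(
            w_edge=rng.normal(0, scale, k_edge),
            w_spd=float(rng.normal(0, scale)),
            sigmas=default_sigmas(K),
            W1=rng.normal(0, scale, (K, K)),
            w2=rng.normal(0, scale, K),
            kernel_form=kernel_form,
        )


@dataclass
class BiasMatrix:
    """Symmetric (a, a) matrix added to attention logits before softmax."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("bias matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("bias matrix has non-finite entries")
        self.values = v


def edge_encoding(graph: MolecularGraph, params: EncodingParams) -> np.ndarray:
    """phi^Edge: path-averaged edge features dotted with w_edge, (a, a)."""
    if len(params.w_edge) != graph.k_edge:
        raise ConfigError(
            f"w_edge has dimension {len(params.w_edge)} but graph k_edge is "
            f"{graph.k_edge}")
    avg = path_averaged_edge_features(graph)
    return avg @ params.w_edge


def spd_encoding(graph: MolecularGraph, params: EncodingParams) -> np.ndarray:
    """phi^SPD: shortest-path distance (sentinel a if unreachable) times w_spd."""
    return spd_matrix(graph).astype(float) * params.w_spd


def kernel_vector(d: float, params: EncodingParams) -> np.ndarray:
    """K-vector psi of radial kernel responses at distance d (Angstrom)."""
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return _kernel(np.asarray(float(d)), params)


def _kernel(d: np.ndarray, params: EncodingParams) -> np.ndarray:
    d = d[..., None]
    if params.kernel_form == "decay":
        return np.exp(-d / params.sigmas)
    mu = np.linspace(0.0, params.d_max, params.K)
    return np.exp(-((d - mu) ** 2) / (2.0 * params.sigmas**2))


def distance_matrix(graph: MolecularGraph) -> np.ndarray:
    if graph.coords is None:
        raise StateError(
            "graph has no 3D coordinates; run generate_conformer first")
    x = np.asarray(graph.coords, dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def distance3d_encoding(graph: MolecularGraph, params: EncodingParams) -> np.ndarray:
    """phi^3D: ReLU(psi(i,j) @ W1) . w2 over Euclidean distances, (a, a)."""
    psi = _kernel(distance_matrix(graph), params)      # (a, a, K)
    hidden = np.maximum(psi @ params.W1, 0.0)
    return hidden @ params.w2


def combined_bias(graph: MolecularGraph, params: EncodingParams,
                  mode: str = "3D") -> BiasMatrix:
    """phi^{2D/3D} = phi^Edge + phi^SPD (+ phi^3D in 3D mode)."""
    if mode not in ("2D", "3D"):
        raise ConfigError(f"mode must be '2D' or '3D', got {mode!r}")
    total = edge_encoding(graph, params) + spd_encoding(graph, params)
    if mode == "3D":
        total = total + distance3d_encoding(graph, params)
    return BiasMatrix(total)
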