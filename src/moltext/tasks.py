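"""Downstream harnesses: retrieval, property prediction, molecule editing.

Retrieval mirrors the standard batched protocol: within seeded batches
(default 64) the true partner of each query must rank first (top-1) or
within the top 20 (R@20) by cosine similarity. Property prediction attaches
a linear (logistic) head to frozen embeddings and reports held-out AUROC.
Editing performs gradient descent in the latent space of an invertible
generator, translating candidate latents into the joint embedding space and
balancing similarity to the original molecule against alignment with a text
prompt; hits are judged by strict descriptor changes (TPSA, HBA/HBD counts,
QED, Wildman-Crippen logP) in the direction each prompt demands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .autodiff import Tensor, cosine
from .errors import PromptError, ValenceError
from .molgraph import MolecularGraph, to_rdkit

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cross-modal retrieval
# ---------------------------------------------------------------------------

@dataclass
class RetrievalReport:
    top1_accuracy: float
    recall_at_20: float
    batch_size: int
    n_batches: int
    seed: int
    direction: str = "M-T"


def _as_matrix(embeddings) -> np.ndarray:
    rows = [getattr(e, "vector", e) for e in embeddings]
    M = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero embedding in retrieval input")
    return M / norms


def retrieval_eval(mol_embeddings, text_embeddings, pairing=None,
                   batch_size: int = 64, n_batches: int = 100, seed: int = 0,
                   direction: str = "M-T") -> RetrievalReport:
    """Top-1 accuracy and R@20 over seeded batches of candidate sets.

    ``pairing`` maps molecule index -> paired text index (identity default).
    Within each batch, each query ranks the batch's opposite-modality
    entries by cosine similarity; a top-1 hit requires its true partner to
    rank first, an R@20 hit requires rank <= 20.
    """
    M = _as_matrix(mol_embeddings)
    T = _as_matrix(text_embeddings)
    n = len(M)
    if len(T) != n:
        raise ValueError("molecule and text lists must have equal length")
    if batch_size > n:
        raise ValueError(f"batch_size {batch_size} exceeds corpus size {n}")
    pairing = np.arange(n) if pairing is None else np.asarray(pairing, dtype=int)
    if sorted(pairing.tolist()) != list(range(n)):
        raise ValueError("pairing must be a bijection over indices")
    if direction not in ("M-T", "T-M"):
        raise ValueError("direction must be 'M-T' or 'T-M'")
    rng = np.random.default_rng(seed)
    top1_hits, r20_hits, total = 0, 0, 0
    for _ in range(n_batches):
        mol_idx = rng.choice(n, size=batch_size, replace=False)
        text_idx = pairing[mol_idx]
        if direction == "M-T":
            sims = M[mol_idx] @ T[text_idx].T     # query rows, candidate cols
        else:
            sims = T[text_idx] @ M[mol_idx].T
        # the true partner of query q sits at column q by construction
        order = np.argsort(-sims, axis=1, kind="stable")
        ranks = np.argmax(order == np.arange(batch_size)[:, None], axis=1)
        top1_hits += int(np.sum(ranks == 0))
        r20_hits += int(np.sum(ranks < 20))
        total += batch_size
    return RetrievalReport(top1_hits / total, r20_hits / total,
                           batch_size, n_batches, seed, direction)


# ---------------------------------------------------------------------------
# Property prediction head
# ---------------------------------------------------------------------------

@dataclass
class PropertyHeadResult:
    coef: np.ndarray
    intercept: np.ndarray
    auroc: float


def train_property_head(embeddings, labels, seed: int = 0) -> PropertyHeadResult:
    """Linear head on an 80/20 seeded split; AUROC on the held-out 20%."""
    X = np.asarray([getattr(e, "vector", e) for e in embeddings], dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; AUROC undefined")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=y)
    clf = LogisticRegression(max_iter=5000, C=100.0)
    clf.fit(Xtr, ytr)
    auroc = float(roc_auc_score(yte, clf.predict_proba(Xte)[:, 1]))
    return PropertyHeadResult(clf.coef_.ravel(), clf.intercept_, auroc)


# ---------------------------------------------------------------------------
# Descriptor panel, hit judging, fingerprints
# ---------------------------------------------------------------------------

@dataclass
class PropertyPanel:
    """Descriptors used by the editing prompts (published definitions)."""

    tpsa: float      # Ertl topological polar surface area, A^2
    hba: int         # Lipinski H-bond acceptor count
    hbd: int         # Lipinski H-bond donor count
    qed: float       # Bickerton drug-likeness in [0, 1]
    wclogp: float    # Wildman-Crippen logP

    def __post_init__(self):
        if self.tpsa < 0 or self.hba < 0 or self.hbd < 0:
            raise ValueError("counts and TPSA must be non-negative")
        if not 0.0 <= self.qed <= 1.0:
            raise ValueError("QED must lie in [0, 1]")


def property_panel(graph: MolecularGraph) -> PropertyPanel:
    mol = to_rdkit(graph)
    try:
        Chem.SanitizeMol(Chem.Mol(mol))
    except Exception as exc:
        raise ValenceError(f"invalid molecule for descriptors: {exc}") from exc
    return PropertyPanel(
        tpsa=float(Descriptors.TPSA(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        qed=float(QED.qed(mol)),
        wclogp=float(Crippen.MolLogP(mol)),
    )


PROMPTS = {
    "more_hba": ("This molecule has more hydrogen bond acceptors.",
                 lambda o, e: e.hba > o.hba),
    "more_hbd": ("This molecule has more hydrogen bond donors.",
                 lambda o, e: e.hbd > o.hbd),
    "drug_like": ("This molecule is like a drug.",
                  lambda o, e: e.qed > o.qed),
    "not_drug_like": ("This molecule is not like a drug.",
                      lambda o, e: e.qed < o.qed),
    "high_permeability": ("This molecule has high permeability.",
                          lambda o, e: e.tpsa < o.tpsa),
    "low_permeability": ("This molecule has low permeability.",
                         lambda o, e: e.tpsa > o.tpsa),
    "soluble": ("This molecule is soluble in water.",
                lambda o, e: e.wclogp < o.wclogp),
    "insoluble": ("This molecule is insoluble in water.",
                  lambda o, e: e.wclogp > o.wclogp),
}


def hit_judge(original: PropertyPanel, edited: PropertyPanel,
              prompt: str) -> bool:
    """Strict-inequality hit rule for one of the eight editing prompts."""
    if prompt not in PROMPTS:
        raise PromptError(
            f"unknown prompt {prompt!r}; valid: {sorted(PROMPTS)}")
    return bool(PROMPTS[prompt][1](original, edited))


def tanimoto_similarity(g1: MolecularGraph, g2: MolecularGraph) -> float:
    """Tanimoto coefficient of 2048-bit hashed path fingerprints."""
    fp1 = Chem.RDKFingerprint(to_rdkit(g1), fpSize=2048)
    fp2 = Chem.RDKFingerprint(to_rdkit(g2), fpSize=2048)
    return float(DataStructs.TanimotoSimilarity(fp1, fp2))


# ---------------------------------------------------------------------------
# Toy invertible generator + latent translator
# ---------------------------------------------------------------------------

class AffineCouplingFlow:
    """Exactly invertible affine-coupling flow over a descriptor vector."""

    def __init__(self, dim: int, n_layers: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.layers = []
        for l in range(n_layers):
            mask = np.zeros(dim, dtype=bool)
            mask[l % 2::2] = True
            d_in, d_out = int(mask.sum()), int((~mask).sum())
            self.layers.append({
                "mask": mask,
                "Ws": rng.normal(0, 0.5, (d_in, d_out)),
                "bs": rng.normal(0, 0.1, d_out),
                "Wt": rng.normal(0, 0.5, (d_in, d_out)),
                "bt": rng.normal(0, 0.1, d_out),
            })

    @staticmethod
    def _scale(x1, L):
        return 0.5 * np.tanh(x1 @ L["Ws"] + L["bs"])   # bounded log-scale

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = np.asarray(x, dtype=float).copy()
        for L in self.layers:
            m = L["mask"]
            x1, x2 = z[m], z[~m]
            z[~m] = x2 * np.exp(self._scale(x1, L)) + (x1 @ L["Wt"] + L["bt"])
        return z

    def inverse(self, z: np.ndarray) -> np.ndarray:
        x = np.asarray(z, dtype=float).copy()
        for L in reversed(self.layers):
            m = L["mask"]
            x1, x2 = x[m], x[~m]
            x[~m] = (x2 - (x1 @ L["Wt"] + L["bt"])) * np.exp(-self._scale(x1, L))
        return x


_GEN_DESC_KEYS = ("tpsa", "hba", "hbd", "qed", "wclogp")


def generator_descriptors(graph: MolecularGraph) -> np.ndarray:
    """Continuous descriptor vector the toy generator operates on."""
    p = property_panel(graph)
    return np.array([p.tpsa, p.hba, p.hbd, p.qed, p.wclogp,
                     graph.atom_count], dtype=float)


class DescriptorGenerator:
    """Toy invertible generator over standardized molecular descriptors.

    ``encode`` maps a molecule's descriptor vector through the flow into the
    latent space; ``decode`` inverts the flow and returns the library
    molecule nearest in descriptor space. Stands in for a full molecular
    flow generator behind the same invertible-generator interface.
    """

    def __init__(self, library, seed: int = 0, n_layers: int = 4):
        if not library:
            raise ValueError("generator needs a non-empty molecule library")
        self.library = list(library)
        D = np.asarray([generator_descriptors(g) for g in self.library])
        self.mean = D.mean(axis=0)
        self.std = np.where(D.std(axis=0) > 1e-9, D.std(axis=0), 1.0)
        self._lib_std = (D - self.mean) / self.std
        self.latent_dim = D.shape[1]
        self.flow = AffineCouplingFlow(self.latent_dim, n_layers, seed)

    def encode(self, graph: MolecularGraph) -> np.ndarray:
        x = (generator_descriptors(graph) - self.mean) / self.std
        return self.flow.forward(x)

    def decode(self, latent: np.ndarray) -> MolecularGraph:
        x = self.flow.inverse(np.asarray(latent, dtype=float))
        d2 = np.sum((self._lib_std - x) ** 2, axis=1)
        return self.library[int(np.argmin(d2))]


class MLPTranslator:
    """2-layer ReLU MLP mapping generator latents into the joint space.

    Weights are fixed after seeded initialization; gradients flow through it
    to the latent during editing, but the translator itself is not trained.
    """

    def __init__(self, latent_dim: int, out_dim: int, hidden: int = 32,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W1 = Tensor(rng.normal(0, 1 / np.sqrt(latent_dim),
                                    (latent_dim, hidden)))
        self.b1 = Tensor(np.zeros(hidden))
        self.W2 = Tensor(rng.normal(0, 1 / np.sqrt(hidden), (hidden, out_dim)))
        self.b2 = Tensor(np.zeros(out_dim))

    def __call__(self, latent: Tensor) -> Tensor:
        return (latent @ self.W1 + self.b1).relu() @ self.W2 + self.b2


class IdentityTranslator:
    def __call__(self, latent: Tensor) -> Tensor:
        return latent


# ---------------------------------------------------------------------------
# Editing optimization
# ---------------------------------------------------------------------------

@dataclass
class EditConfig:
    steps: int = 600
    step_size: float = 0.05
    lambda_text: float = 1.0
    generator: object = None        # invertible-generator handle
    translator: object = None       # latent -> joint-space callable
    latent_dim: int = 6
    init_from_molecule: bool = False
    init_scale: float = 1.0         # std of the Gaussian latent init

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.step_size < 0:
            raise ValueError("step_size must be non-negative")
        if self.lambda_text < 0:
            raise ValueError("lambda_text must be non-negative")


@dataclass
class EditResult:
    latent: np.ndarray
    loss_trace: list
    decoded: MolecularGraph | None = None


def edit_optimize(mol_embedding, text_embedding, config: EditConfig,
                  seed: int = 0, init_latent=None) -> EditResult:
    """Gradient descent on a generator latent against two cosine losses.

    loss(z) = (1 - cos(c, z_mol)) + lambda * (1 - cos(c, z_text)) with
    c = translator(z). The latent starts from seeded Gaussian noise (or the
    provided ``init_latent``); the step size is halved whenever a step would
    increase the loss, so the final loss never exceeds the initial one.
    """
    zm = np.asarray(getattr(mol_embedding, "vector", mol_embedding), float)
    zt = np.asarray(getattr(text_embedding, "vector", text_embedding), float)
    translator = config.translator or IdentityTranslator()
    dim = (config.generator.latent_dim if config.generator is not None
           else config.latent_dim)
    if init_latent is not None:
        latent = np.asarray(init_latent, dtype=float).copy()
    else:
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal(dim) * config.init_scale

    def eval_loss(z, with_grad):
        zt_t = Tensor(z, requires_grad=with_grad)
        c = translator(zt_t)
        loss = (1.0 - cosine(c, Tensor(zm))) \
            + config.lambda_text * (1.0 - cosine(c, Tensor(zt)))
        if with_grad:
            loss.backward()
            return float(loss.data), zt_t.grad
        return float(loss.data), None

    step = config.step_size
    cur, _ = eval_loss(latent, False)
    trace = [cur]
    for i in range(config.steps):
        _, grad = eval_loss(latent, True)
        if grad is None or not np.all(np.isfinite(grad)):
            raise RuntimeError(f"non-finite gradient at editing step {i}")
        moved = False
        for _ in range(30):
            cand = latent - step * grad
            val, _ = eval_loss(cand, False)
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite loss at editing step {i}")
            if val <= cur or step == 0.0:
                break
            step *= 0.5
        else:
            val = cur
            cand = latent
        if val <= cur:
            latent, cur, moved = cand, val, True
        trace.append(cur)
        if not moved and step == 0.0:
            pass  # flat trace by contract when step_size is zero
    decoded = config.generator.decode(latent) if config.generator is not None else None
    return EditResult(latent, trace, decoded)


# edited molecule should have a HIGHER (+1) or LOWER (-1) descriptor value
_PROMPT_DIRECTION = {
    "more_hba": ("hba", +1), "more_hbd": ("hbd", +1),
    "drug_like": ("qed", +1), "not_drug_like": ("qed", -1),
    "high_permeability": ("tpsa", -1), "low_permeability": ("tpsa", +1),
    "soluble": ("wclogp", -1), "insoluble": ("wclogp", +1),
}


def prompt_anchor_embedding(generator: DescriptorGenerator, translator,
                            prompt: str, top_fraction: float = 0.25) -> np.ndarray:
    """Joint-space anchor for a prompt: the mean translated latent of the
    library molecules that best exemplify the prompt's descriptor direction.

    Optimizing a candidate latent toward this anchor pulls the decoded
    molecule toward exemplars of the desired property, giving the toy
    editing harness a real gradient signal in descriptor space.
    """
    if prompt not in _PROMPT_DIRECTION:
        raise PromptError(f"unknown prompt {prompt!r}; valid: {sorted(PROMPTS)}")
    attr, sign = _PROMPT_DIRECTION[prompt]
    translator = translator or IdentityTranslator()
    scores = [sign * getattr(property_panel(g), attr) for g in generator.library]
    k = max(1, int(np.ceil(top_fraction * len(scores))))
    best = np.argsort(scores)[::-1][:k]
    anchors = [translator(Tensor(generator.encode(generator.library[i]))).data
               for i in best]
    return np.mean(anchors, axis=0)


@dataclass
class EditingReport:
    prompt: str
    hit_ratio: float            # percentage in [0, 100]
    mean_similarity: float      # mean Tanimoto original vs edited
    hits: list = field(default_factory=list)
    similarities: list = field(default_factory=list)
    final_losses: list = field(default_factory=list)


def editing_benchmark(molecules, prompt: str, config: EditConfig,
                      seed: int = 0, mol_embed=None, text_embed=None) -> EditingReport:
    """Run the editing loop over molecules and judge descriptor hits.

    ``mol_embed(graph)`` and ``text_embed(prompt_text)`` supply joint-space
    embeddings; by default the toy generator's translated latents serve as
    molecule embeddings and the prompt anchor must be supplied explicitly.
    Decode failures count as misses and are logged, never fatal.
    """
    if prompt not in PROMPTS:
        raise PromptError(f"unknown prompt {prompt!r}; valid: {sorted(PROMPTS)}")
    if not molecules:
        raise ValueError("molecule list is empty")
    if config.generator is None:
        raise ValueError("editing_benchmark needs a generator with a decode path")
    translator = config.translator or IdentityTranslator()
    if mol_embed is None:
        def mol_embed(g):
            return translator(Tensor(config.generator.encode(g))).data
    if text_embed is None:
        raise ValueError("text_embed callable (prompt anchor) is required")
    prompt_text = PROMPTS[prompt][0]
    z_text = np.asarray(getattr(text_embed(prompt_text), "vector",
                                text_embed(prompt_text)), dtype=float)
    hits, sims, finals = [], [], []
    for i, g in enumerate(molecules):
        z_mol = np.asarray(getattr(mol_embed(g), "vector", mol_embed(g)), float)
        init = config.generator.encode(g) if config.init_from_molecule else None
        res = edit_optimize(z_mol, z_text, config,
                            seed=(seed * 9973 + i) % 2**31, init_latent=init)
        finals.append(res.loss_trace[-1])
        try:
            edited = res.decoded
            hit = hit_judge(property_panel(g), property_panel(edited), prompt)
            sim = tanimoto_similarity(g, edited)
        except Exception as exc:   # decode/descriptor failure -> miss
            log.warning("edit of molecule %d failed: %s", i, exc)
            hit, sim = False, float("nan")
        hits.append(bool(hit))
        sims.append(sim)
    valid = [s for s in sims if np.isfinite(s)]
    return EditingReport(
        prompt=prompt,
        hit_ratio=100.0 * sum(hits) / len(hits),
        mean_similarity=float(np.mean(valid)) if valid else float("nan"),
        hits=hits, similarities=sims, final_losses=finals)
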