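"""Graph attention autoencoder (GATE) over a similarity graph.

Each node carries an attribute vector (by default its association profile).
An encoder layer transforms every node, scores each neighbor pair with a
sigmoid attention logit

    c_ij = sigmoid(v_s . tanh(W h_i) + v_r . tanh(W h_j)),

softmax-normalises the logits over the neighbor set N_i (which always
contains i itself), and aggregates

    h_i' = sum_{j in N_i} alpha_ij tanh(W h_j).

The decoder mirrors the encoder back to the attribute dimension, and the
loss combines attribute reconstruction with a graph-structure term,

    L = sum_i ||x_i - xhat_i||^2
        - lambda * sum_i sum_{j in N_i} log sigmoid(h_i . h_j).

Training is plain full-batch gradient descent with adaptive moments (Adam);
gradients are hand-derived and checked against finite differences in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "AttributedGraph",
    "GateConfig",
    "GateModel",
    "EmbeddingSet",
    "PairDataset",
    "build_graph",
    "attention_weights",
    "encode",
    "decode",
    "gate_loss",
    "train_gate",
    "make_pair_features",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class AttributedGraph:
    """Sparsified neighbor structure plus node attributes.

    ``neighbor_sets[i]`` always contains ``i``; ``mask`` is the dense boolean
    incidence (mask[i, j] iff j in N_i).
    """

    names: list[str]
    neighbor_sets: list[np.ndarray]
    X: np.ndarray
    mask: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.names)


@dataclass
class GateConfig:
    embedding_dim: int = 64
    hidden_dims: tuple[int, ...] = ()  # extra encoder layers before the last
    epochs: int = 200
    learning_rate: float = 1e-3
    lam: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be positive")


@dataclass
class GateModel:
    """Encoder/decoder parameters.  Layer k of the encoder holds
    (W, v_s, v_r); the decoder mirrors the encoder dimensions in reverse."""

    enc: list[dict[str, np.ndarray]]
    dec: list[dict[str, np.ndarray]]
    lam: float
    dims: list[int]  # [attr_dim, *hidden, embedding_dim]

    def parameters(self):
        for layer in self.enc + self.dec:
            for name in ("W", "vs", "vr"):
                yield layer, name


@dataclass
class EmbeddingSet:
    names: list[str]
    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape[0] != len(self.names):
            raise ValueError("embedding rows do not match names")
        if not np.isfinite(self.H).all():
            raise ValueError("non-finite embedding values")

    @property
    def dim(self) -> int:
        return self.H.shape[1]


@dataclass
class PairDataset:
    """Concatenated microbe+disease features for microbe-disease pairs.

    ``labels``: 1 = known association (positive), 0 = negative,
    -1 = unlabeled.
    """

    pairs: np.ndarray  # (P, 2) of (disease_idx, microbe_idx)
    X: np.ndarray  # (P, a)
    labels: np.ndarray  # (P,) in {1, 0, -1}

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.pairs) == len(self.X) == len(self.labels)):
            raise ValueError("pairs, features and labels must align")

    @property
    def feature_width(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# graph construction


def build_graph(S: SimilarityMatrix, attributes: np.ndarray,
                k_neighbors: int) -> AttributedGraph:
    """Top-k sparsification of a dense similarity matrix, plus self-loops.

    N_i = {i} union the k_neighbors highest-similarity partners of i, ties
    broken toward the lower index.
    """
    n = S.n
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n={n}")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    X = np.asarray(attributes, dtype=float)
    if X.shape[0] != n:
        raise ValueError("attribute rows do not match similarity size")

    mask = np.zeros((n, n), dtype=bool)
    neighbor_sets = []
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        # stable sort by descending similarity; ties keep lower index first
        order = others[np.lexsort((others, -S.S[i, others]))]
        nbrs = np.sort(np.append(order[:k_neighbors], i))
        neighbor_sets.append(nbrs)
        mask[i, nbrs] = True
    return AttributedGraph(list(S.names), neighbor_sets, X, mask)


# ---------------------------------------------------------------------------
# forward / backward of one attention layer


def _layer_forward(Hin: np.ndarray, W: np.ndarray, vs: np.ndarray,
                   vr: np.ndarray, mask: np.ndarray):
    Z = np.tanh(Hin @ W.T)
    s = Z @ vs
    r = Z @ vr
    C = _sigmoid(s[:, None] + r[None, :])
    E = np.where(mask, np.exp(C), 0.0)
    A = E / E.sum(axis=1, keepdims=True)
    Hout = A @ Z
    cache = (Hin, W, vs, vr, mask, Z, C, A)
    return Hout, A, cache


def _layer_backward(dHout: np.ndarray, cache):
    Hin, W, vs, vr, mask, Z, C, A = cache
    dA = np.where(mask, dHout @ Z.T, 0.0)
    dZ = A.T @ dHout
    rowdot = (A * dA).sum(axis=1, keepdims=True)
    dC = A * (dA - rowdot)  # softmax jacobian, zero off-mask
    D = dC * C * (1.0 - C)  # through the sigmoid logit
    ds = D.sum(axis=1)
    dr = D.sum(axis=0)
    dZ = dZ + np.outer(ds, vs) + np.outer(dr, vr)
    dvs = Z.T @ ds
    dvr = Z.T @ dr
    dPre = dZ * (1.0 - Z ** 2)
    dW = dPre.T @ Hin
    dHin = dPre @ W
    return dHin, {"W": dW, "vs": dvs, "vr": dvr}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# model construction and public forward passes


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def init_model(attr_dim: int, config: GateConfig) -> GateModel:
    dims = [attr_dim, *config.hidden_dims, config.embedding_dim]
    rng = np.random.default_rng(config.seed)
    enc, dec = [], []
    for din, dout in zip(dims[:-1], dims[1:]):
        enc.append({"W": _glorot(rng, dout, din),
                    "vs": rng.uniform(-0.1, 0.1, dout),
                    "vr": rng.uniform(-0.1, 0.1, dout)})
    for dout, din in zip(dims[:-1][::-1], dims[1:][::-1]):
        dec.append({"W": _glorot(rng, dout, din),
                    "vs": rng.uniform(-0.1, 0.1, dout),
                    "vr": rng.uniform(-0.1, 0.1, dout)})
    return GateModel(enc=enc, dec=dec, lam=config.lam, dims=dims)


def attention_weights(model: GateModel, layer: int, graph: AttributedGraph,
                      representations: np.ndarray,
                      direction: str = "encode") -> np.ndarray:
    """Dense attention matrix alpha for one layer; rows sum to 1 over N_i."""
    if direction not in ("encode", "decode"):
        raise ValueError("direction must be 'encode' or 'decode'")
    params = (model.enc if direction == "encode" else model.dec)[layer]
    _, A, _ = _layer_forward(np.asarray(representations, dtype=float),
                             params["W"], params["vs"], params["vr"],
                             graph.mask)
    return A


def encode(model: GateModel, graph: AttributedGraph):
    """Run the encoder; returns (per-layer representations, EmbeddingSet).

    The per-layer list starts with the attributes h^(0) = x."""
    H = graph.X
    layers = [H]
    for k, p in enumerate(model.enc):
        H, _, _ = _layer_forward(H, p["W"], p["vs"], p["vr"], graph.mask)
        if not np.isfinite(H).all():
            raise FloatingPointError(f"non-finite values in encoder layer {k}")
        layers.append(H)
    return layers, EmbeddingSet(list(graph.names), H)


def decode(model: GateModel, embeddings: EmbeddingSet,
           graph: AttributedGraph) -> np.ndarray:
    """Run the decoder from the embeddings back to attribute space."""
    H = embeddings.H
    for k, p in enumerate(model.dec):
        H, _, _ = _layer_forward(H, p["W"], p["vs"], p["vr"], graph.mask)
        if not np.isfinite(H).all():
            raise FloatingPointError(f"non-finite values in decoder layer {k}")
    return H


def gate_loss(model: GateModel, graph: AttributedGraph,
              embeddings: EmbeddingSet, reconstructions: np.ndarray) -> float:
    """Reconstruction loss plus lambda-weighted structure loss."""
    if model.lam < 0:
        raise ValueError("lambda must be non-negative")
    X, Xhat, H = graph.X, np.asarray(reconstructions), embeddings.H
    if Xhat.shape != X.shape:
        raise ValueError("reconstruction shape mismatch")
    recon = float(((X - Xhat) ** 2).sum())
    logits = H @ H.T
    # -log sigmoid(t) = log(1 + exp(-t)), computed stably
    neglog = np.logaddexp(0.0, -logits)
    structure = float(neglog[graph.mask].sum())
    return recon + model.lam * structure


def _loss_and_grads(model: GateModel, graph: AttributedGraph):
    X, mask = graph.X, graph.mask
    H = X
    enc_caches = []
    for p in model.enc:
        H, _, cache = _layer_forward(H, p["W"], p["vs"], p["vr"], mask)
        enc_caches.append(cache)
    Hemb = H
    dec_caches = []
    for p in model.dec:
        H, _, cache = _layer_forward(H, p["W"], p["vs"], p["vr"], mask)
        dec_caches.append(cache)
    Xhat = H

    R = Xhat - X
    recon = float((R ** 2).sum())
    logits = Hemb @ Hemb.T
    neglog = np.logaddexp(0.0, -logits)
    structure = float(neglog[mask].sum())
    loss = recon + model.lam * structure

    grads_dec: list[dict[str, np.ndarray]] = []
    dH = 2.0 * R
    for cache in reversed(dec_caches):
        dH, g = _layer_backward(dH, cache)
        grads_dec.append(g)
    grads_dec.reverse()

    # structure term gradient wrt the embeddings
    Sg = _sigmoid(logits)
    B = np.where(mask, -model.lam * (1.0 - Sg), 0.0)
    dH = dH + (B + B.T) @ Hemb

    grads_enc: list[dict[str, np.ndarray]] = []
    for cache in reversed(enc_caches):
        dH, g = _layer_backward(dH, cache)
        grads_enc.append(g)
    grads_enc.reverse()

    return loss, grads_enc, grads_dec


def train_gate(graph: AttributedGraph, config: GateConfig):
    """Train the autoencoder; returns (model, EmbeddingSet, loss trace).

    Deterministic for a given seed: initialisation, the (full-batch) update
    order and all arithmetic are seed-controlled.
    """
    model = init_model(graph.X.shape[1], config)
    opt = _Adam(model, config.learning_rate)
    losses: list[float] = []
    for epoch in range(config.epochs):
        loss, genc, gdec = _loss_and_grads(model, graph)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        losses.append(loss)
        opt.step(genc, gdec)
    _, emb = encode(model, graph)
    logger.debug("gate training: %d epochs, loss %.4g -> %.4g",
                 config.epochs, losses[0] if losses else float("nan"),
                 losses[-1] if losses else float("nan"))
    return model, emb, np.array(losses)


class _Adam:
    def __init__(self, model: GateModel, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.items()}
                  for layer in model.enc + model.dec]
        self.v = [{k: np.zeros_like(v) for k, v in layer.items()}
                  for layer in model.enc + model.dec]

    def step(self, grads_enc, grads_dec):
        self.t += 1
        layers = self.model.enc + self.model.dec
        grads = grads_enc + grads_dec
        for i, (layer, g) in enumerate(zip(layers, grads)):
            for k in ("W", "vs", "vr"):
                self.m[i][k] = self.beta1 * self.m[i][k] + (1 - self.beta1) * g[k]
                self.v[i][k] = self.beta2 * self.v[i][k] + (1 - self.beta2) * g[k] ** 2
                mhat = self.m[i][k] / (1 - self.beta1 ** self.t)
                vhat = self.v[i][k] / (1 - self.beta2 ** self.t)
                layer[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# pair features


def make_pair_features(microbe_emb: EmbeddingSet, disease_emb: EmbeddingSet,
                       pairs: np.ndarray,
                       labels: np.ndarray | None = None) -> PairDataset:
    """Concatenate [microbe embedding || disease embedding] per pair.

    ``pairs`` rows are (disease_idx, microbe_idx); feature width is
    d_microbe + d_disease (128 under the 64-dimensional defaults).
    """
    pairs = np.asarray(pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    if len(pairs) and (pairs[:, 0].max() >= len(disease_emb.names)
                       or pairs[:, 0].min() < 0):
        raise IndexError("unknown disease index in pairs")
    if len(pairs) and (pairs[:, 1].max() >= len(microbe_emb.names)
                       or pairs[:, 1].min() < 0):
        raise IndexError("unknown microbe index in pairs")
    X = np.hstack([microbe_emb.H[pairs[:, 1]], disease_emb.H[pairs[:, 0]]])
    if labels is None:
        labels = np.full(len(pairs), -1, dtype=int)
    return PairDataset(pairs=pairs, X=X, labels=labels)
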