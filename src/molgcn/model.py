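"""Residual graph-convolutional network for arbitrary-sized molecular graphs.

Forward computation, per molecule:

1. input map          A_i^(1) = F(A_i^(0) W^(0) + b^(0))
2. message            C_ij^(l) = G( [A_i | B(i,j) | A_j] W^(l) + b^(l) )
3. residual update    A_i^(l+1) = A_i^(l) + V^(l) max_j C_ij^(l)
                      (element-wise max over bonded neighbours j; an atom with
                      no neighbours pools the zero vector, so its row passes
                      through unchanged)
4. readout            Y = sum_i A_i^(m+1)  concatenated with global features M
5. dense head         hidden leaky-ReLU layer of width h, sigmoid output of
                      width c (one probability per task)

F, G and the head's hidden activation are the leaky ReLU.  Dropout (inverted
scaling) is applied in training mode to A^(1), to each post-convolution A, and
to the head's hidden activations.

The module provides both a readable per-operation reference path
(:func:`initial_hidden`, :func:`pair_message`, :func:`conv_step`,
:func:`readout`, :func:`head_forward`) and a packed-batch path
(:func:`pack_graphs`, :func:`batch_forward`, :func:`batch_backward`) that
concatenates many molecules into one flat graph for efficient NumPy training.
The two paths compute the same function; the test suite asserts it.

Gradients are analytic (hand-derived backpropagation) and are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.special import expit

from .featurize import MolGraph


# ---------------------------------------------------------------------------
# activations


def leaky_relu(x, slope: float):
    """x for x >= 0, slope*x otherwise, element-wise."""
    if not 0.0 < slope < 1.0:
        raise ValueError(f"leaky ReLU slope must be in (0,1), got {slope}")
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, 1.0, slope)


# ---------------------------------------------------------------------------
# parameters


@dataclasses.dataclass
class ConvLayerParams:
    W: np.ndarray  # (2k + d_bond, k) message weights
    b: np.ndarray  # (k,)
    V: np.ndarray  # (k, k) square projection of the pooled messages


@dataclasses.dataclass
class ModelParams:
    """All learnable tensors plus the featurization fingerprint they assume."""

    W0: np.ndarray                      # (d_atom, k)
    b0: np.ndarray                      # (k,)
    layers: list                        # [ConvLayerParams] * m
    Wh: np.ndarray                      # (k + d_mol, h)
    bh: np.ndarray                      # (h,)
    Wo: np.ndarray                      # (h, c)
    bo: np.ndarray                      # (c,)
    leaky_slope: float = 0.01
    fingerprint: dict = dataclasses.field(default_factory=dict)
    # training-split (mean, scale) for global molecular features, or None
    mol_standardization: Optional[tuple] = None

    @property
    def k(self) -> int:
        return self.W0.shape[1]

    @property
    def m(self) -> int:
        return len(self.layers)

    @property
    def h(self) -> int:
        return self.Wh.shape[1]

    @property
    def c(self) -> int:
        return self.Wo.shape[1]

    @property
    def d_mol(self) -> int:
        return self.Wh.shape[0] - self.k

    def param_items(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (name, array) for every learnable block, in a fixed order."""
        yield "W0", self.W0
        yield "b0", self.b0
        for l, layer in enumerate(self.layers, start=1):
            yield f"W_{l}", layer.W
            yield f"b_{l}", layer.b
            yield f"V_{l}", layer.V
        yield "Wh", self.Wh
        yield "bh", self.bh
        yield "Wo", self.Wo
        yield "bo", self.bo

    def copy(self) -> "ModelParams":
        return ModelParams(
            W0=self.W0.copy(), b0=self.b0.copy(),
            layers=[ConvLayerParams(l.W.copy(), l.b.copy(), l.V.copy())
                    for l in self.layers],
            Wh=self.Wh.copy(), bh=self.bh.copy(),
            Wo=self.Wo.copy(), bo=self.bo.copy(),
            leaky_slope=self.leaky_slope,
            fingerprint=dict(self.fingerprint),
            mol_standardization=None if self.mol_standardization is None else
            (np.array(self.mol_standardization[0]), np.array(self.mol_standardization[1])),
        )


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


def init_params(dims: tuple[int, int, int], c: int, *, k: int = 64, h: int = 128,
                m: int = 2, seed=0, leaky_slope: float = 0.01,
                fingerprint: Optional[dict] = None) -> ModelParams:
    """Seeded parameter initialization: symmetric uniform scaled by fan-in,
    zero biases.  ``dims`` is ``(d_atom, d_bond, d_mol)``."""
    d_atom, d_bond, d_mol = dims
    for name, v in (("d_atom", d_atom), ("k", k), ("h", h), ("m", m), ("c", c)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layers = []
    msg_width = 2 * k + d_bond
    for _ in range(m):
        layers.append(ConvLayerParams(
            W=_uniform(rng, msg_width, (msg_width, k)),
            b=np.zeros(k),
            V=_uniform(rng, k, (k, k)),
        ))
    return ModelParams(
        W0=_uniform(rng, d_atom, (d_atom, k)), b0=np.zeros(k),
        layers=layers,
        Wh=_uniform(rng, k + d_mol, (k + d_mol, h)), bh=np.zeros(h),
        Wo=_uniform(rng, h, (h, c)), bo=np.zeros(c),
        leaky_slope=leaky_slope,
        fingerprint=dict(fingerprint or {}),
    )


# ---------------------------------------------------------------------------
# reference per-operation path (readable; used as the compositional oracle)


def initial_hidden(A0: np.ndarray, params: ModelParams) -> np.ndarray:
    """Input map: row i is F(A_i^(0); W^(0)), output width k."""
    A0 = np.atleast_2d(np.asarray(A0, dtype=float))
    if A0.shape[1] != params.W0.shape[0]:
        raise ValueError(f"atom-feature width {A0.shape[1]} does not match "
                         f"W0 input width {params.W0.shape[0]}")
    return leaky_relu(A0 @ params.W0 + params.b0, params.leaky_slope)


def pair_message(A_i: np.ndarray, B_ij: np.ndarray, A_j: np.ndarray,
                 layer: ConvLayerParams, slope: float = 0.01) -> np.ndarray:
    """Message from neighbour j to atom i: G([A_i | B(i,j) | A_j]; W).  Not
    symmetric in (i, j): the concatenation is ordered."""
    u = np.concatenate([np.asarray(A_i, float), np.asarray(B_ij, float),
                        np.asarray(A_j, float)])
    if u.shape[0] != layer.W.shape[0]:
        raise ValueError(f"message width {u.shape[0]} does not match "
                         f"W input width {layer.W.shape[0]}")
    return leaky_relu(u @ layer.W + layer.b, slope)


def conv_step(graph: MolGraph, A: np.ndarray, layer: ConvLayerParams,
              slope: float = 0.01) -> np.ndarray:
    """One residual convolution: A_i + V . (element-wise max over neighbour
    messages).  Atoms with no neighbours pool the zero vector and pass through
    unchanged."""
    A = np.asarray(A, dtype=float)
    n, k = A.shape
    pooled = np.zeros((n, k))
    incoming: dict[int, list] = {}
    # message pooled at atom i from neighbour j is G([A_i | B(i,j) | A_j])
    for (i, j) in graph.edges:
        B = graph.bond_features[_edge_row(graph, i, j)]
        incoming.setdefault(int(i), []).append(pair_message(A[i], B, A[j], layer, slope))
        incoming.setdefault(int(j), []).append(pair_message(A[j], B, A[i], layer, slope))
    for i, msgs in incoming.items():
        pooled[i] = np.max(np.stack(msgs), axis=0)
    return A + pooled @ layer.V.T


def _edge_row(graph: MolGraph, i, j) -> int:
    lo, hi = (i, j) if i < j else (j, i)
    hits = np.where((graph.edges[:, 0] == lo) & (graph.edges[:, 1] == hi))[0]
    if len(hits) != 1:
        raise ValueError(f"edge ({i},{j}) not found exactly once")
    return int(hits[0])


def readout(A_final: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Sum the atom representations and append the global feature vector."""
    return np.concatenate([np.asarray(A_final, float).sum(axis=0),
                           np.asarray(M, float)])


def head_forward(Y: np.ndarray, params: ModelParams,
                 dropout_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Dense head: leaky-ReLU hidden layer of width h, sigmoid output of
    width c."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[-1] != params.Wh.shape[0]:
        raise ValueError(f"readout width {Y.shape[-1]} does not match head "
                         f"input width {params.Wh.shape[0]}")
    hidden = leaky_relu(Y @ params.Wh + params.bh, params.leaky_slope)
    if dropout_mask is not None:
        hidden = hidden * dropout_mask
    return expit(hidden @ params.Wo + params.bo)


def forward(graph: MolGraph, params: ModelParams, mode: str = "eval",
            dropout_rng: Optional[np.random.Generator] = None,
            dropout_rate: float = 0.0) -> np.ndarray:
    """Full forward pass on one molecule; returns c task probabilities.

    Deterministic in eval mode; in train mode dropout masks are drawn from
    ``dropout_rng``.
    """
    probs, _ = batch_forward(pack_graphs([graph],
                                         mol_standardization=params.mol_standardization),
                             params, mode=mode, rng=dropout_rng,
                             dropout_rate=dropout_rate)
    return probs[0]


# ---------------------------------------------------------------------------
# packed-batch path


@dataclasses.dataclass
class GraphBatch:
    """Several molecules concatenated into one flat graph.

    Directed edges are stored sorted by destination atom so neighbourhood
    max-pooling reduces over contiguous segments.
    """

    X: np.ndarray            # (N, d_atom) atom features, molecules contiguous
    mol_ptr: np.ndarray      # (B+1,) atom-offset of each molecule
    mol_index: np.ndarray    # (N,) molecule id per atom
    dst: np.ndarray          # (E2,) destination atom of each directed edge
    src: np.ndarray          # (E2,) source atom
    bondf: np.ndarray        # (E2, d_bond)
    seg_starts: np.ndarray   # (S,) first directed-edge row of each pooled atom
    seg_atoms: np.ndarray    # (S,) atom id of each segment
    seg_counts: np.ndarray   # (S,)
    M: np.ndarray            # (B, d_mol)
    labels: Optional[np.ndarray]  # (B, c)
    mask: Optional[np.ndarray]    # (B, c)

    @property
    def n_mols(self) -> int:
        return len(self.mol_ptr) - 1

    @property
    def n_atoms(self) -> int:
        return self.X.shape[0]


def pack_graphs(graphs: Sequence[MolGraph],
                mol_standardization: Optional[tuple] = None) -> GraphBatch:
    """Concatenate molecules into one packed batch.

    ``mol_standardization``, when given as ``(mean, scale)``, is applied to the
    raw global molecular features (models carry their training-split
    statistics).
    """
    offsets = np.concatenate([[0], np.cumsum([g.n_atoms for g in graphs])])
    X = np.concatenate([g.atom_features for g in graphs], axis=0)
    mol_index = np.repeat(np.arange(len(graphs)), [g.n_atoms for g in graphs])

    dsts, srcs, bfs = [], [], []
    for off, g in zip(offsets[:-1], graphs):
        if len(g.edges):
            e = g.edges + off
            dsts.append(np.concatenate([e[:, 0], e[:, 1]]))
            srcs.append(np.concatenate([e[:, 1], e[:, 0]]))
            bfs.append(np.concatenate([g.bond_features, g.bond_features], axis=0))
    d_bond = graphs[0].bond_features.shape[1]
    if dsts:
        dst = np.concatenate(dsts)
        src = np.concatenate(srcs)
        bondf = np.concatenate(bfs, axis=0)
        order = np.argsort(dst, kind="stable")
        dst, src, bondf = dst[order], src[order], bondf[order]
        seg_atoms, seg_starts, seg_counts = np.unique(
            dst, return_index=True, return_counts=True)
    else:
        dst = src = np.zeros(0, dtype=np.int64)
        bondf = np.zeros((0, d_bond))
        seg_atoms = seg_starts = seg_counts = np.zeros(0, dtype=np.int64)

    M = np.stack([g.mol_features for g in graphs])
    if mol_standardization is not None and M.shape[1]:
        mean, scale = mol_standardization
        M = (M - np.asarray(mean, float)) / np.asarray(scale, float)

    labels = mask = None
    if all(g.labels is not None for g in graphs):
        labels = np.stack([g.labels for g in graphs])
        mask = np.stack([
            g.label_mask if g.label_mask is not None else np.ones_like(g.labels)
            for g in graphs])
    return GraphBatch(X=X, mol_ptr=offsets, mol_index=mol_index, dst=dst,
                      src=src, bondf=bondf, seg_starts=seg_starts,
                      seg_atoms=seg_atoms, seg_counts=seg_counts, M=M,
                      labels=labels, mask=mask)


def _segment_max(C: np.ndarray, batch: GraphBatch, n_atoms: int) -> np.ndarray:
    pooled = np.zeros((n_atoms, C.shape[1]))
    if len(batch.seg_starts):
        pooled[batch.seg_atoms] = np.maximum.reduceat(C, batch.seg_starts, axis=0)
    return pooled


def _segment_max_backward(C: np.ndarray, pooled: np.ndarray,
                          d_pooled: np.ndarray, batch: GraphBatch) -> np.ndarray:
    """Route pooled-gradient rows to the first maximal message per segment and
    channel (ties broken toward the earliest edge)."""
    if not len(batch.seg_starts):
        return np.zeros_like(C)
    is_max = C == pooled[batch.dst]
    cs = np.cumsum(is_max, axis=0)
    base = np.where(batch.seg_starts[:, None] > 0,
                    cs[batch.seg_starts - 1], 0)            # (S, k)
    seg_id = np.repeat(np.arange(len(batch.seg_starts)), batch.seg_counts)
    first = is_max & ((cs - base[seg_id]) == 1)
    return first * d_pooled[batch.dst]


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    # inverted dropout: surviving activations scaled by 1/(1-rate)
    return (rng.random(shape) >= rate) / (1.0 - rate)


def batch_forward(batch: GraphBatch, params: ModelParams, mode: str = "eval",
                  rng: Optional[np.random.Generator] = None,
                  dropout_rate: float = 0.0):
    """Forward pass over a packed batch.

    Returns ``(probs, cache)`` where ``probs`` is (B, c) and ``cache`` holds
    the intermediates :func:`batch_backward` needs.  ``mode='train'`` draws
    dropout masks from ``rng``; eval mode is deterministic.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    train = mode == "train" and dropout_rate > 0.0
    if train and rng is None:
        raise ValueError("train-mode dropout requires an rng")
    slope = params.leaky_slope
    if batch.X.shape[1] != params.W0.shape[0]:
        raise ValueError(f"atom-feature width {batch.X.shape[1]} does not match "
                         f"model input width {params.W0.shape[0]} "
                         f"(config/params mismatch)")
    if batch.M.shape[1] != params.d_mol:
        raise ValueError(f"global-feature width {batch.M.shape[1]} does not "
                         f"match model d_mol {params.d_mol}")

    cache: dict = {"layers": []}
    Z0 = batch.X @ params.W0 + params.b0
    A = leaky_relu(Z0, slope)
    D0 = _dropout_mask(rng, A.shape, dropout_rate) if train else None
    if D0 is not None:
        A = A * D0
    cache["Z0"], cache["D0"] = Z0, D0

    for layer in params.layers:
        U = np.concatenate([A[batch.dst], batch.bondf, A[batch.src]], axis=1)
        Z = U @ layer.W + layer.b
        C = leaky_relu(Z, slope)
        pooled = _segment_max(C, batch, batch.n_atoms)
        A_new = A + pooled @ layer.V.T
        D = _dropout_mask(rng, A_new.shape, dropout_rate) if train else None
        if D is not None:
            A_new = A_new * D
        cache["layers"].append({"U": U, "Z": Z, "C": C, "pooled": pooled, "D": D})
        A = A_new

    cache["A_final"] = A
    S = np.add.reduceat(A, batch.mol_ptr[:-1], axis=0)
    Y = np.concatenate([S, batch.M], axis=1)
    Zh = Y @ params.Wh + params.bh
    H = leaky_relu(Zh, slope)
    Dh = _dropout_mask(rng, H.shape, dropout_rate) if train else None
    if Dh is not None:
        H = H * Dh
    Zo = H @ params.Wo + params.bo
    probs = expit(Zo)
    cache.update({"Y": Y, "Zh": Zh, "H": H, "Dh": Dh, "Zo": Zo, "probs": probs})
    return probs, cache


def batch_backward(batch: GraphBatch, params: ModelParams, cache: dict,
                   d_logits: np.ndarray) -> dict:
    """Backpropagate ``d_logits`` (gradient of the loss w.r.t. the sigmoid
    pre-activations, shape (B, c)) through the cached forward pass.  Returns a
    dict keyed like :meth:`ModelParams.param_items`."""
    slope = params.leaky_slope
    grads: dict[str, np.ndarray] = {}

    H, Y, Zh = cache["H"], cache["Y"], cache["Zh"]
    grads["Wo"] = H.T @ d_logits
    grads["bo"] = d_logits.sum(axis=0)
    dH = d_logits @ params.Wo.T
    if cache["Dh"] is not None:
        dH = dH * cache["Dh"]
    dZh = dH * _leaky_grad(Zh, slope)
    grads["Wh"] = Y.T @ dZh
    grads["bh"] = dZh.sum(axis=0)
    dY = dZh @ params.Wh.T

    k = params.k
    dS = dY[:, :k]
    dA = np.repeat(dS, np.diff(batch.mol_ptr), axis=0)

    for l in range(params.m, 0, -1):
        layer = params.layers[l - 1]
        lc = cache["layers"][l - 1]
        if lc["D"] is not None:
            dA = dA * lc["D"]
        # residual: A_new = A_prev + pooled @ V.T  (then dropout, handled above)
        d_pooled = dA @ layer.V
        grads[f"V_{l}"] = dA.T @ lc["pooled"]
        dC = _segment_max_backward(lc["C"], lc["pooled"], d_pooled, batch)
        dZ = dC * _leaky_grad(lc["Z"], slope)
        grads[f"W_{l}"] = lc["U"].T @ dZ
        grads[f"b_{l}"] = dZ.sum(axis=0)
        dU = dZ @ layer.W.T
        d_bond = batch.bondf.shape[1]
        np.add.at(dA, batch.dst, dU[:, :k])
        np.add.at(dA, batch.src, dU[:, k + d_bond:])

    if cache["D0"] is not None:
        dA = dA * cache["D0"]
    dZ0 = dA * _leaky_grad(cache["Z0"], slope)
    grads["W0"] = batch.X.T @ dZ0
    grads["b0"] = dZ0.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_checkpoint(params: ModelParams, path) -> None:
    """Serialize parameters plus the featurization fingerprint to an ``.npz``
    archive; loads fail loudly on fingerprint mismatch."""
    arrays = {name: arr for name, arr in params.param_items()}
    meta = {
        "m": params.m,
        "leaky_slope": params.leaky_slope,
        "fingerprint": params.fingerprint,
        "has_mol_standardization": params.mol_standardization is not None,
    }
    if params.mol_standardization is not None:
        arrays["mol_std_mean"] = np.asarray(params.mol_standardization[0], float)
        arrays["mol_std_scale"] = np.asarray(params.mol_standardization[1], float)
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path, expected_fingerprint: Optional[dict] = None) -> ModelParams:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if expected_fingerprint is not None and meta["fingerprint"] != expected_fingerprint:
            raise ValueError(
                "checkpoint featurization fingerprint does not match the "
                f"active configuration:\n saved: {meta['fingerprint']}\n "
                f"expected: {expected_fingerprint}")
        layers = [ConvLayerParams(W=data[f"W_{l}"], b=data[f"b_{l}"], V=data[f"V_{l}"])
                  for l in range(1, meta["m"] + 1)]
        std = None
        if meta["has_mol_standardization"]:
            std = (data["mol_std_mean"], data["mol_std_scale"])
        return ModelParams(W0=data["W0"], b0=data["b0"], layers=layers,
                           Wh=data["Wh"], bh=data["bh"], Wo=data["Wo"],
                           bo=data["bo"], leaky_slope=meta["leaky_slope"],
                           fingerprint=meta["fingerprint"],
                           mol_standardization=std)
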