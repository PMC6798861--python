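"""Index-based splitting, ADAM training with dropout, per-epoch validation
selection, and seed ensembles.

The dataset is split by *index* — the order the samples appear on disk — into
contiguous train/validation/test blocks (default 80/10/10).  Each network
trains by minimizing the (optionally class-weighted) summed cross-entropy with
ADAM, evaluating mean validation AUC after every epoch and keeping the
parameters of the best epoch (earliest on ties).  An ensemble is the same
procedure repeated with seeds ``base_seed + 0 .. base_seed + size - 1``.

All randomness (initialization, per-epoch batch order, dropout masks) derives
from the per-model seed through independent ``SeedSequence`` streams, so a run
is bit-reproducible from ``(dataset, config, seed)``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional, Sequence

import numpy as np

from .featurize import FeatureConfig, MolGraph, feature_dimensions
from .losses import ClassWeights, bce_logit_grad, bce_loss, class_weights, weighted_bce_loss
from .model import (ModelParams, batch_backward, batch_forward, init_params,
                    pack_graphs)
from .evaluation import auc_score

logger = logging.getLogger("molgcn")


@dataclasses.dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the reference protocol: 200 epochs, batch size 20,
    learning rate 1e-3 (ADAM), 10% dropout, 80/10/10 index split, ensembles of
    ten networks, two convolution layers of width 64 and one dense hidden
    layer of width 128.
    """

    epochs: int = 200
    batch_size: int = 20
    learning_rate: float = 1e-3
    dropout_rate: float = 0.10
    split_fractions: tuple = (0.8, 0.1, 0.1)
    loss: str = "standard"            # "standard" | "weighted"
    ensemble_size: int = 10
    base_seed: int = 0
    feature_level: int = 5
    conv_layers: int = 2              # m
    hidden_width: int = 64            # k
    dense_width: int = 128            # h
    leaky_slope: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.ensemble_size < 1:
            raise ValueError("epochs, batch_size and ensemble_size must be >= 1")
        fr = tuple(self.split_fractions)
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must be three positives summing "
                             f"to 1, got {fr}")
        if self.loss not in ("standard", "weighted"):
            raise ValueError(f"loss must be 'standard' or 'weighted', got {self.loss!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclasses.dataclass
class TrainHistory:
    train_loss: list                  # per-epoch summed training loss
    val_mean_auc: list                # per-epoch validation mean AUC
    best_epoch: int                   # argmax of val_mean_auc, earliest on ties
    best_val_auc: float
    excluded_val_tasks: list          # task indices unevaluable on the split


def index_split(n: int, fractions: Sequence[float] = (0.8, 0.1, 0.1)):
    """Contiguous, order-preserving split: first ``floor(f_train*n)`` indices
    train, next ``floor(f_valid*n)`` validation, remainder test."""
    if n < 3:
        raise ValueError(f"need n >= 3 to split, got {n}")
    f_train, f_valid, _ = fractions
    n_train = int(np.floor(f_train * n))
    n_valid = int(np.floor(f_valid * n))
    n_test = n - n_train - n_valid
    if min(n_train, n_valid, n_test) < 1:
        raise ValueError(f"n={n} leaves an empty split for fractions {tuple(fractions)}")
    idx = np.arange(n)
    return idx[:n_train], idx[n_train:n_train + n_valid], idx[n_train + n_valid:]


def _labels_of(graphs: Sequence[MolGraph]):
    if any(g.labels is None for g in graphs):
        raise ValueError("all graphs must carry labels for training")
    y = np.stack([g.labels for g in graphs])
    mask = np.stack([g.label_mask if g.label_mask is not None
                     else np.ones_like(g.labels) for g in graphs])
    return y, mask


def _evaluable_tasks(y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tasks with both classes among observed labels."""
    obs_pos = ((y == 1) & (mask == 1)).sum(axis=0)
    obs_neg = ((y == 0) & (mask == 1)).sum(axis=0)
    return np.where((obs_pos > 0) & (obs_neg > 0))[0]


def _mean_val_auc(probs: np.ndarray, y: np.ndarray, mask: np.ndarray,
                  tasks: np.ndarray) -> float:
    aucs = []
    for j in tasks:
        obs = mask[:, j] == 1
        aucs.append(auc_score(y[obs, j], probs[obs, j]))
    return float(np.mean(aucs))


class _Adam:
    def __init__(self, params: ModelParams, cfg: TrainConfig):
        self.lr, self.b1, self.b2, self.eps = (cfg.learning_rate, cfg.adam_beta1,
                                               cfg.adam_beta2, cfg.adam_eps)
        self.m = {n: np.zeros_like(a) for n, a in params.param_items()}
        self.v = {n: np.zeros_like(a) for n, a in params.param_items()}
        self.t = 0

    def step(self, params: ModelParams, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, arr in params.param_items():
            g = grads[name]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            arr -= self.lr * (self.m[name] / bc1) / (np.sqrt(self.v[name] / bc2) + self.eps)


def fit_mol_standardization(graphs: Sequence[MolGraph]):
    """Mean/scale of the global molecular features over ``graphs`` (training
    split); near-constant features get scale 1 to avoid division blow-up."""
    M = np.stack([g.mol_features for g in graphs])
    if M.shape[1] == 0:
        return None
    mean = M.mean(axis=0)
    scale = M.std(axis=0)
    scale[scale < 1e-8] = 1.0
    return mean, scale


def train_model(dataset: Sequence[MolGraph], config: TrainConfig, seed: int,
                feature_config: Optional[FeatureConfig] = None):
    """Train one network; returns ``(best_params, TrainHistory)``.

    Deterministic given ``(dataset, config, seed)``: initialization, batch
    order and dropout masks all derive from the seed.
    """
    n = len(dataset)
    train_idx, val_idx, _ = index_split(n, config.split_fractions)
    train_graphs = [dataset[i] for i in train_idx]
    val_graphs = [dataset[i] for i in val_idx]
    y_tr, m_tr = _labels_of(train_graphs)
    y_va, m_va = _labels_of(val_graphs)
    c = y_tr.shape[1]

    d_atom = dataset[0].atom_features.shape[1]
    d_bond = dataset[0].bond_features.shape[1]
    d_mol = dataset[0].mol_features.shape[0]
    if feature_config is not None:
        dims = feature_dimensions(feature_config)
        if dims != (d_atom, d_bond, d_mol):
            raise ValueError(f"graphs have widths {(d_atom, d_bond, d_mol)} but "
                             f"feature config implies {dims}")
        fingerprint = feature_config.fingerprint()
    else:
        fingerprint = {"level": config.feature_level}
    fingerprint = dict(fingerprint,
                       dims=[d_atom, d_bond, d_mol],
                       k=config.hidden_width, h=config.dense_width,
                       m=config.conv_layers, c=c)

    ss = np.random.SeedSequence(seed)
    init_ss, shuffle_ss, dropout_ss = ss.spawn(3)
    params = init_params((d_atom, d_bond, d_mol), c, k=config.hidden_width,
                         h=config.dense_width, m=config.conv_layers,
                         seed=np.random.default_rng(init_ss),
                         leaky_slope=config.leaky_slope,
                         fingerprint=fingerprint)
    params.mol_standardization = fit_mol_standardization(train_graphs)

    weights: Optional[ClassWeights] = None
    if config.loss == "weighted":
        weights = class_weights(y_tr, m_tr)

    val_tasks = _evaluable_tasks(y_va, m_va)
    excluded = sorted(set(range(c)) - set(val_tasks.tolist()))
    if excluded:
        warnings.warn(f"validation tasks {excluded} are single-class and are "
                      "excluded from the selection metric")
    if len(val_tasks) == 0:
        raise ValueError("no validation task has both classes; cannot select a model")

    val_batch = pack_graphs(val_graphs, params.mol_standardization)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)
    adam = _Adam(params, config)

    history = TrainHistory(train_loss=[], val_mean_auc=[], best_epoch=-1,
                           best_val_auc=-np.inf, excluded_val_tasks=excluded)
    best_params = params.copy()
    n_tr = len(train_graphs)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, config.batch_size):
            sel = order[start:start + config.batch_size]
            batch = pack_graphs([train_graphs[i] for i in sel],
                                params.mol_standardization)
            probs, cache = batch_forward(batch, params, mode="train",
                                         rng=dropout_rng,
                                         dropout_rate=config.dropout_rate)
            if weights is None:
                epoch_loss += bce_loss(batch.labels, probs, batch.mask)
            else:
                epoch_loss += weighted_bce_loss(batch.labels, probs, weights,
                                                batch.mask)
            d_logits = bce_logit_grad(batch.labels, probs, batch.mask, weights)
            grads = batch_backward(batch, params, cache, d_logits)
            adam.step(params, grads)

        val_probs, _ = batch_forward(val_batch, params, mode="eval")
        val_auc = _mean_val_auc(val_probs, y_va, m_va, val_tasks)
        history.train_loss.append(epoch_loss)
        history.val_mean_auc.append(val_auc)
        if val_auc > history.best_val_auc:
            history.best_val_auc = val_auc
            history.best_epoch = epoch
            best_params = params.copy()
        logger.debug("seed=%d epoch=%d loss=%.4f val_auc=%.4f",
                     seed, epoch, epoch_loss, val_auc)
    return best_params, history


def train_ensemble(dataset: Sequence[MolGraph], config: TrainConfig,
                   feature_config: Optional[FeatureConfig] = None):
    """Train ``config.ensemble_size`` networks with seeds ``base_seed + i``;
    returns a list of ``(ModelParams, TrainHistory)``."""
    out = []
    for i in range(config.ensemble_size):
        out.append(train_model(dataset, config, config.base_seed + i,
                               feature_config))
        logger.info("trained ensemble member %d/%d (best val AUC %.4f at epoch %d)",
                    i + 1, config.ensemble_size, out[-1][1].best_val_auc,
                    out[-1][1].best_epoch)
    return out
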