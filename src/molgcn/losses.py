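"""Standard and class-frequency-weighted binary cross-entropy.

Both losses are *sums* over samples and tasks (the learning rate absorbs the
scale); missing labels are masked out of the loss and out of the weight
estimation.  The weighted variant multiplies the positive-label log term of
task j by the observed negative fraction of that task and the negative-label
term by the observed positive fraction, so misclassified rare samples dominate
the total loss.  For a perfectly balanced task both weights are 0.5 and the
weighted loss is exactly half the standard one.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np

#: probabilities are clipped to [EPS, 1-EPS] before any log
EPS = 1e-7


@dataclasses.dataclass
class ClassWeights:
    """Per-task loss weights; ``w_pos[j] + w_neg[j] == 1``.

    ``degenerate`` lists tasks whose observed labels were single-class (their
    weights collapse to 0/1).
    """

    w_pos: np.ndarray
    w_neg: np.ndarray
    degenerate: list = dataclasses.field(default_factory=list)


def _check_shapes(y, yhat, mask):
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError(f"label shape {y.shape} != prediction shape {yhat.shape}")
    if mask is None:
        mask = np.ones_like(y)
    else:
        mask = np.asarray(mask, float)
        if mask.shape != y.shape:
            raise ValueError(f"mask shape {mask.shape} != label shape {y.shape}")
    return y, yhat, mask


def bce_loss(y: np.ndarray, yhat: np.ndarray,
             mask: Optional[np.ndarray] = None) -> float:
    """Masked binary cross-entropy, summed over samples and tasks."""
    y, yhat, mask = _check_shapes(y, yhat, mask)
    p = np.clip(yhat, EPS, 1.0 - EPS)
    terms = -y * np.log(p) - (1.0 - y) * np.log1p(-p)
    return float(np.sum(mask * terms))


def class_weights(labels: np.ndarray, mask: Optional[np.ndarray] = None) -> ClassWeights:
    """Estimate per-task weights from observed label frequencies.

    ``w_pos[j]`` is the observed fraction of negatives for task j, ``w_neg[j]``
    the fraction of positives.  Intended to be computed on the *training*
    split only.  Raises on a task with zero observed labels; warns on a
    single-class task (its weights become 0/1).
    """
    y = np.atleast_2d(np.asarray(labels, float))
    if mask is None:
        mask = np.ones_like(y)
    else:
        mask = np.atleast_2d(np.asarray(mask, float))
        if mask.shape != y.shape:
            raise ValueError("mask shape does not match labels")
    n_obs = mask.sum(axis=0)
    if np.any(n_obs == 0):
        bad = np.where(n_obs == 0)[0].tolist()
        raise ValueError(f"tasks {bad} have zero observed labels")
    pos_frac = (y * mask).sum(axis=0) / n_obs
    w_pos = 1.0 - pos_frac
    w_neg = pos_frac
    degenerate = np.where((pos_frac == 0.0) | (pos_frac == 1.0))[0].tolist()
    if degenerate:
        warnings.warn(f"tasks {degenerate} have single-class observed labels; "
                      "their loss weights are degenerate (0/1)",
                      stacklevel=2)
    return ClassWeights(w_pos=w_pos, w_neg=w_neg, degenerate=degenerate)


def weighted_bce_loss(y: np.ndarray, yhat: np.ndarray, weights: ClassWeights,
                      mask: Optional[np.ndarray] = None) -> float:
    """Class-frequency-weighted masked binary cross-entropy (summed)."""
    y, yhat, mask = _check_shapes(y, yhat, mask)
    if len(weights.w_pos) != y.shape[-1]:
        raise ValueError(f"weights cover {len(weights.w_pos)} tasks, "
                         f"batch has {y.shape[-1]}")
    p = np.clip(yhat, EPS, 1.0 - EPS)
    terms = (-weights.w_pos * y * np.log(p)
             - weights.w_neg * (1.0 - y) * np.log1p(-p))
    return float(np.sum(mask * terms))


def bce_logit_grad(y: np.ndarray, yhat: np.ndarray,
                   mask: Optional[np.ndarray] = None,
                   weights: Optional[ClassWeights] = None) -> np.ndarray:
    """Gradient of the (optionally weighted) summed BCE w.r.t. the sigmoid
    pre-activations: mask * (-w_pos*y*(1-p) + w_neg*(1-y)*p)."""
    y, yhat, mask = _check_shapes(y, yhat, mask)
    if weights is None:
        w_pos = w_neg = np.ones(y.shape[-1])
    else:
        w_pos, w_neg = weights.w_pos, weights.w_neg
    return mask * (-w_pos * y * (1.0 - yhat) + w_neg * (1.0 - y) * yhat)
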