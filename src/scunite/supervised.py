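"""Supervised classification loss on labeled source cells.

A single affine + softmax head on the bottleneck gives the latent space
basic cluster-recognition ability during pretraining: cells of the same
reference type are pulled together, and target cells resembling a known
type land near it. The loss is the mean cross-entropy over labeled cells
only; target cells contribute nothing.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad

#: probability clamp applied before the logarithm
CLASS_EPS = 1e-8


def classification_loss(c: np.ndarray, label_index: np.ndarray) -> float:
    """Mean cross-entropy -ln c[i, y_i] over labeled cells.

    Parameters
    ----------
    c
        Row-stochastic probability matrix, labeled cells x n_types.
    label_index
        Integer type index per included cell; every cell must be labeled.
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(label_index)
    if c.ndim != 2 or len(y) != c.shape[0]:
        raise ValueError("probability matrix and labels are misaligned")
    if (y < 0).any() or (y >= c.shape[1]).any():
        raise ValueError("label index out of range (unlabeled cell passed in?)")
    picked = np.clip(c[np.arange(len(y)), y], CLASS_EPS, 1.0)
    return float(-np.mean(np.log(picked)))


def classification_loss_t(log_probs: ad.Tensor, label_index: np.ndarray) -> ad.Tensor:
    """Differentiable mean cross-entropy from log-softmax outputs.

    Cells with ``label_index < 0`` (unlabeled) are excluded from the mean
    and contribute no gradient; at least one labeled cell is required.
    """
    y = np.asarray(label_index)
    labeled = y >= 0
    if not labeled.any():
        raise ValueError("no labeled cells in batch")
    onehot = np.zeros(log_probs.shape, dtype=log_probs.data.dtype)
    onehot[np.where(labeled)[0], y[labeled]] = 1.0
    return -(log_probs * onehot).sum() * (1.0 / labeled.sum())
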