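"""Self-supervised pairwise similarity fusion.

Cell pairs are pseudo-labeled similar/dissimilar from the cosine similarity
of their latent codes under a pair of moving thresholds: pairs above the
upper threshold u(t) are positives, pairs below the lower threshold l(t)
negatives, pairs in between are left out. Where both cells carry reference
labels the labels override the thresholds. The thresholds tighten linearly
over the fusion epochs,

    u(t) = 0.95 - 0.0045 t,    l(t) = 0.455 + 0.00045 t,    t = 1..100,

so training proceeds from easy pairs to hard pairs and stops when
u(t) < l(t) (at t = 100 both reach 0.5). The loss is a binary cross-entropy
treating the (clamped) cosine value itself as the predicted probability of
being a positive pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad

#: clamp keeping cosine values usable as Bernoulli probabilities
S_EPS = 1e-6


@dataclass
class SimilarityState:
    """Minibatch similarity matrix with its pseudo-labels and thresholds."""

    S: np.ndarray
    R_hat: np.ndarray
    selected: np.ndarray
    u: float
    l: float
    t: int


def cosine_similarity(z: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; unit diagonal, symmetric."""
    z = np.asarray(z, dtype=float)
    norms = np.linalg.norm(z, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm latent vector")
    zn = z / norms[:, None]
    S = zn @ zn.T
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def threshold_schedule(t: int) -> tuple[float, float]:
    """Linear threshold schedule; fusion is active while u(t) >= l(t)."""
    if t < 1:
        raise ValueError("epoch counter starts at 1")
    return 0.95 - 0.0045 * t, 0.455 + 0.00045 * t


def build_pseudo_labels(S: np.ndarray, labels, u: float, l: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-label matrix R_hat and its selected mask for one minibatch.

    ``labels`` is a per-cell sequence with ``None`` for unlabeled cells.
    Pairs where both cells are labeled are always selected with
    R_hat = 1{y_i = y_j}; other pairs use the threshold band. Self-pairs
    are never selected.
    """
    if u < l:
        raise ValueError("u < l: fusion schedule exhausted")
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    lab = np.asarray(list(labels), dtype=object)
    has = np.array([x is not None for x in lab])
    both = has[:, None] & has[None, :]
    same = np.zeros((n, n), dtype=bool)
    if has.any():
        li = lab[has]
        same_sub = li[:, None] == li[None, :]
        ix = np.where(has)[0]
        same[np.ix_(ix, ix)] = same_sub

    R = np.zeros((n, n), dtype=np.int8)
    sel = np.zeros((n, n), dtype=np.int8)
    # label rule overrides the thresholds
    R[both & same] = 1
    sel[both] = 1
    # threshold rule for pairs with at least one unlabeled cell
    free = ~both
    sel[free & (S > u)] = 1
    R[free & (S > u)] = 1
    sel[free & (S < l)] = 1
    np.fill_diagonal(sel, 0)
    np.fill_diagonal(R, 0)
    return R, sel


def self_supervised_loss(S: np.ndarray, R_hat: np.ndarray,
                         selected: np.ndarray) -> float:
    """Pairwise binary cross-entropy, summed over selected pairs and
    averaged over cells.

    Averaging over cells (not pairs) makes the loss scale with the number
    of selected partners per cell, so it is naturally larger than the
    reconstruction loss and the weight grid {0.1, 0.01, 0.001} brings the
    two to the same order of magnitude.
    """
    sel = np.asarray(selected, dtype=bool)
    if not sel.any():
        warnings.warn("no selected pairs; self-supervised loss is 0")
        return 0.0
    s = np.clip(np.asarray(S, dtype=float)[sel], S_EPS, 1.0 - S_EPS)
    r = np.asarray(R_hat, dtype=float)[sel]
    total = float(np.sum(-r * np.log(s) - (1.0 - r) * np.log(1.0 - s)))
    return total / S.shape[0]


def self_supervised_loss_t(z: ad.Tensor, R_hat: np.ndarray,
                           selected: np.ndarray) -> ad.Tensor:
    """Differentiable pairwise BCE on cosine similarities of ``z`` rows
    (summed over selected pairs, averaged over cells)."""
    sel = np.asarray(selected, dtype=float)
    if sel.sum() == 0:
        warnings.warn("no selected pairs; self-supervised loss is 0")
        return ad.Tensor(0.0)
    zn = ad.normalize_rows(z)
    S = ad.clip(zn @ zn.T, S_EPS, 1.0 - S_EPS)
    r = np.asarray(R_hat, dtype=z.data.dtype)
    bce = -(ad.log(S) * r + ad.log(1.0 - S) * (1.0 - r))
    return (bce * sel).sum() * (1.0 / z.shape[0])
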