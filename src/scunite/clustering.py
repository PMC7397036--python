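"""Entropy-regularized soft k-means on the unit sphere.

With latent codes z_i and centers v_j constrained to unit norm, the
objective

    min_w sum_i sum_j 2 w_ij (1 - z_i' v_j) + sigma * w_ij ln w_ij,
    s.t. sum_j w_ij = 1,

uses the spherical distance identity ||z - v||^2 = 2 (1 - z'v) on the unit
sphere. For fixed z and v the memberships have the closed form

    w_ij = exp(-2 (1 - z_i' v_j) / sigma) / sum_l exp(-2 (1 - z_i' v_l) / sigma),

a softmax over (negative) distances whose temperature sigma (default 1)
controls the softness; sigma -> 0 recovers hard nearest-center assignment.
Training minimizes sum_j 2 w_ij (1 - z_i' v_j) averaged over cells with w
held fixed, moving both the network (through z) and the centers v.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from . import _autodiff as ad


@dataclass
class ClusterModel:
    """Unit-norm centers, soft memberships and the entropy weight."""

    v: np.ndarray
    w: np.ndarray
    sigma: float = 1.0
    k: int = 0
    annotation: dict = field(default_factory=dict)

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.k == 0:
            self.k = self.v.shape[0]
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _ensure_unit_rows(x: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        warnings.warn(f"{what} rows are not unit-norm; renormalizing")
        x = x / np.maximum(norms[:, None], 1e-12)
    return x


def soft_assignments(z: np.ndarray, v: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Closed-form memberships (max-subtraction log-sum-exp for stability)."""
    z = _ensure_unit_rows(np.asarray(z, dtype=float), "latent")
    v = _ensure_unit_rows(np.asarray(v, dtype=float), "center")
    logits = -2.0 * (1.0 - z @ v.T) / sigma
    return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))


def clustering_loss(z: np.ndarray, v: np.ndarray, w_fixed: np.ndarray) -> float:
    """Mean over cells of sum_j 2 w_ij (1 - z_i' v_j), with w constant."""
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w_fixed, dtype=float)
    if w.shape != (z.shape[0], v.shape[0]):
        raise ValueError("membership matrix shape mismatch")
    return float(np.mean(np.sum(2.0 * w * (1.0 - z @ v.T), axis=1)))


def clustering_loss_t(z: ad.Tensor, v: ad.Tensor, w_fixed: np.ndarray) -> ad.Tensor:
    """Differentiable clustering loss; gradients flow to z and v only."""
    zn = ad.normalize_rows(z)
    dots = zn @ v.T
    w = np.asarray(w_fixed, dtype=z.data.dtype)
    return ((2.0 * (1.0 - dots)) * w).sum(axis=1).mean()


def init_centers(z: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Standard k-means (k-means++, 20 restarts) on unit-normalized z."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] < k:
        raise ValueError(f"need at least k={k} cells, got {z.shape[0]}")
    zn = z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
    km = KMeans(n_clusters=k, n_init=20, random_state=int(seed) % (2 ** 31))
    km.fit(zn)
    v = km.cluster_centers_
    return v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)


def hard_labels(w: np.ndarray) -> np.ndarray:
    """Maximum-membership cluster per cell; ties go to the smaller index."""
    return np.argmax(np.asarray(w, dtype=float), axis=1)
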