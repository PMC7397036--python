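"""Three-stage training schedule.

Stage 1 (pretrain) minimizes the ZINB reconstruction loss L1 plus the
supervised cross-entropy L2 on labeled cells. Stage 2 (similarity fusion)
minimizes L1 + lambda1 * L3, where L3 is the pairwise pseudo-label loss
under the moving thresholds; one threshold step per fusion epoch, stopping
when the band closes. Stage 3 (cluster refinement) initializes centers by
standard k-means on the fused latent space, then minimizes
L1 + lambda2 * L4 with memberships recomputed from the full data at each
epoch start, until hard assignments stop changing. L1 is kept in every
stage to preserve the global structure of the data and avoid overfitting.

The loss weights lambda1/lambda2 are picked from the grid
{0.1, 0.01, 0.001} so that the weighted term matches L1's order of
magnitude on a warm-up batch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .clustering import (ClusterModel, clustering_loss, clustering_loss_t,
                         hard_labels, init_centers, soft_assignments)
from .data_io import ProcessedData
from .network import LatentCode, NetworkConfig, ZINBAutoencoder
from .selfsup import (build_pseudo_labels, cosine_similarity,
                      self_supervised_loss, self_supervised_loss_t,
                      threshold_schedule)
from .supervised import classification_loss_t
from .zinb import reconstruction_loss, zinb_nll_t

LAMBDA_GRID = (0.1, 0.01, 0.001)


@dataclass
class TrainPlan:
    """Stage schedule, loss weights and ablation switches."""

    lambda1: float | None = None      # None -> magnitude-matching grid rule
    lambda2: float | None = None
    epochs_pretrain: int = 500
    epochs_fuse: int = 100
    epochs_cluster: int = 200
    use_supervised: bool = True
    use_selfsup: bool = True
    use_cluster: bool = True
    sigma: float = 1.0
    seed: int = 0
    convergence_tol: float = 1e-3     # fraction of cells changing cluster


@dataclass
class PipelineResult:
    latent: LatentCode
    clusters: ClusterModel
    cluster_labels: np.ndarray
    log: pd.DataFrame
    network: ZINBAutoencoder
    lambda1: float | None = None
    lambda2: float | None = None


def choose_lambda(L1_value: float, Lother_value: float,
                  grid=LAMBDA_GRID) -> float:
    """Grid element matching lambda * Lother to L1's order of magnitude.

    Minimizes |log10(lambda * Lother) - log10(L1)|; ties favor the larger
    lambda.
    """
    if L1_value <= 0 or Lother_value <= 0:
        raise ValueError("loss values must be positive")
    best, best_d = None, np.inf
    for lam in sorted(grid, reverse=True):
        d = abs(np.log10(lam * Lother_value) - np.log10(L1_value))
        if d < best_d:
            best, best_d = lam, d
    return best


def _epoch_batches(n: int, size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return [perm[i:i + size] for i in range(0, n, size)]


def full_latent(net: ZINBAutoencoder, data: ProcessedData,
                batch_size: int = 1024) -> np.ndarray:
    """Encode all cells (no gradients), in chunks."""
    outs = [net.encode(data.x_input[i:i + batch_size],
                       data.batch_onehot[i:i + batch_size])
            for i in range(0, data.n_cells, batch_size)]
    return np.vstack(outs)


def evaluate_nll(net: ZINBAutoencoder, data: ProcessedData,
                 batch_size: int = 512) -> float:
    """Mean ZINB negative log-likelihood over all cells (no gradients)."""
    total, n = 0.0, 0
    for i in range(0, data.n_cells, batch_size):
        sl = slice(i, i + batch_size)
        _, params, _ = net.predict(data.x_input[sl], data.batch_onehot[sl],
                                   data.size_factor[sl])
        m = data.x_raw[sl].size
        total += reconstruction_loss(data.x_raw[sl], params) * m
        n += m
    return total / n


def predict_type_probs(net: ZINBAutoencoder, data: ProcessedData,
                       batch_size: int = 1024) -> np.ndarray:
    """Per-cell source-type probabilities from the classification head."""
    outs = []
    for i in range(0, data.n_cells, batch_size):
        sl = slice(i, i + batch_size)
        _, _, probs = net.predict(data.x_input[sl], data.batch_onehot[sl],
                                  data.size_factor[sl])
        outs.append(probs)
    return np.vstack(outs)


def _check_finite(value: float, stage: str, epoch: int):
    if not np.isfinite(value):
        raise RuntimeError(f"loss diverged (NaN/inf) at {stage}, epoch {epoch}")


def run_pipeline(data: ProcessedData, k: int, plan: TrainPlan | None = None,
                 config: NetworkConfig | None = None,
                 checkpoint_dir=None) -> PipelineResult:
    """Run the full pretrain -> fuse -> cluster schedule.

    ``k`` is the user-supplied total cluster count over the source/target
    union. Deterministic given ``plan.seed`` up to floating-point
    non-associativity.
    """
    plan = plan or TrainPlan()
    config = config or NetworkConfig()
    config.seed = plan.seed
    net = ZINBAutoencoder(data.n_hvg, data.n_batches,
                          max(data.n_source_types, 1), config)
    rng = np.random.default_rng(plan.seed)
    log: list[dict] = []
    train_labels = data.label_index  # -1 marks cells excluded from L2
    str_labels = [str(li) if li >= 0 else None for li in train_labels]

    def forward(idx, noise_sd: float = 0.0):
        x = data.x_input[idx]
        if noise_sd > 0:
            x = x + noise_sd * rng.standard_normal(x.shape)
        return net.forward(x, data.batch_onehot[idx], data.size_factor[idx],
                           training=True)

    # ---------------- stage 1: pretrain (L1 + L2) ----------------------
    opt = ad.Adam(net.parameters(), lr=config.learning_rate,
                  clip_norm=config.grad_clip_norm)
    for epoch in range(1, plan.epochs_pretrain + 1):
        l1s, l2s = [], []
        for idx in _epoch_batches(data.n_cells, config.minibatch, rng):
            out = forward(idx, noise_sd=config.denoise_sd)
            l1 = zinb_nll_t(data.x_raw[idx], out["pi"], out["mu"], out["theta"])
            loss = l1
            if plan.use_supervised and (train_labels[idx] >= 0).any():
                l2 = classification_loss_t(out["log_probs"], train_labels[idx])
                loss = loss + l2
                l2s.append(l2.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
            l1s.append(l1.item())
        _check_finite(np.mean(l1s), "pretrain", epoch)
        log.append({"stage": "pretrain", "epoch": epoch,
                    "l1": float(np.mean(l1s)),
                    "l2": float(np.mean(l2s)) if l2s else np.nan})
    if checkpoint_dir:
        net.save(os.path.join(checkpoint_dir, "stage1_pretrain.npz"))

    lambda1 = plan.lambda1
    # ---------------- stage 2: similarity fusion (L1 + lambda1*L3) -----
    if plan.use_selfsup:
        opt = ad.Adam(net.parameters(), lr=config.learning_rate,
                      clip_norm=config.grad_clip_norm)
        for t in range(1, plan.epochs_fuse + 1):
            u, l = threshold_schedule(t)
            if u < l:
                break
            l1s, l3s, nsel, npos = [], [], 0, 0
            for idx in _epoch_batches(data.n_cells, config.minibatch, rng):
                out = forward(idx)
                S = cosine_similarity(out["z"].data)
                R, sel = build_pseudo_labels(
                    S, [str_labels[i] for i in idx], u, l)
                if lambda1 is None:
                    l1_val = zinb_nll_t(data.x_raw[idx], out["pi"], out["mu"],
                                        out["theta"]).item()
                    l3_val = self_supervised_loss(S, R, sel)
                    lambda1 = (choose_lambda(l1_val, l3_val)
                               if l3_val > 0 else LAMBDA_GRID[1])
                l1 = zinb_nll_t(data.x_raw[idx], out["pi"], out["mu"],
                                out["theta"])
                l3 = self_supervised_loss_t(out["z"], R, sel)
                loss = l1 + lambda1 * l3
                opt.zero_grad()
                loss.backward()
                opt.step()
                l1s.append(l1.item())
                l3s.append(l3.item())
                nsel += int(sel.sum())
                npos += int((R * sel).sum())
            _check_finite(np.mean(l1s), "fuse", t)
            log.append({"stage": "fuse", "epoch": t, "l1": float(np.mean(l1s)),
                        "l3": float(np.mean(l3s)), "u": u, "l": l,
                        "n_selected": nsel,
                        "pos_frac": npos / nsel if nsel else np.nan,
                        "lambda1": lambda1})
        if checkpoint_dir:
            net.save(os.path.join(checkpoint_dir, "stage2_fuse.npz"))

    # ---------------- stage 3: cluster refinement (L1 + lambda2*L4) ----
    z_all = full_latent(net, data)
    z_unit = LatentCode(z_all).unit
    centers = init_centers(z_all, k, seed=plan.seed)

    if not plan.use_cluster:
        w = soft_assignments(z_unit, centers, plan.sigma)
        labels = hard_labels(w)
        log.append({"stage": "cluster", "epoch": 0, "flag": "no-refinement"})
        return PipelineResult(
            latent=LatentCode(z_all),
            clusters=ClusterModel(v=centers, w=w, sigma=plan.sigma, k=k),
            cluster_labels=labels, log=pd.DataFrame(log), network=net,
            lambda1=lambda1, lambda2=None)

    v = ad.Tensor(centers.astype(net.dtype), requires_grad=True)
    opt = ad.Adam(net.parameters() + [v], lr=config.learning_rate,
                  clip_norm=config.grad_clip_norm)
    lambda2 = plan.lambda2
    prev = None
    for epoch in range(1, plan.epochs_cluster + 1):
        z_all = full_latent(net, data)
        z_unit = LatentCode(z_all).unit
        # re-seed centers that lost all expected members
        w = soft_assignments(z_unit, v.data, plan.sigma)
        empty = np.where(w.sum(axis=0) < 1.0)[0]
        if len(empty) > 0:
            assigned = hard_labels(w)
            dist = 1.0 - np.einsum("ij,ij->i", z_unit, v.data[assigned])
            for j in empty:
                far = int(np.argmax(dist))
                v.data[j] = z_unit[far]
                dist[far] = -np.inf
            w = soft_assignments(z_unit, v.data, plan.sigma)
        labels = hard_labels(w)
        change = float(np.mean(labels != prev)) if prev is not None else np.nan
        prev = labels
        if lambda2 is None:
            idx0 = np.arange(min(config.minibatch, data.n_cells))
            out0 = forward(idx0)
            l1_val = zinb_nll_t(data.x_raw[idx0], out0["pi"], out0["mu"],
                                out0["theta"]).item()
            l4_val = clustering_loss(z_unit[idx0], v.data, w[idx0])
            lambda2 = (choose_lambda(l1_val, l4_val)
                       if l4_val > 0 else LAMBDA_GRID[1])
        if not np.isnan(change) and change < plan.convergence_tol:
            log.append({"stage": "cluster", "epoch": epoch,
                        "label_change": float(change), "flag": "converged",
                        "lambda2": lambda2})
            break
        l1s, l4s = [], []
        for idx in _epoch_batches(data.n_cells, config.minibatch, rng):
            out = forward(idx)
            l1 = zinb_nll_t(data.x_raw[idx], out["pi"], out["mu"],
                            out["theta"])
            l4 = clustering_loss_t(out["z"], v, w[idx])
            loss = l1 + lambda2 * l4
            opt.zero_grad()
            loss.backward()
            opt.step()
            # keep centers on the unit sphere under SGD
            v.data /= np.maximum(
                np.linalg.norm(v.data, axis=1, keepdims=True), 1e-12)
            l1s.append(l1.item())
            l4s.append(l4.item())
        _check_finite(np.mean(l1s), "cluster", epoch)
        log.append({"stage": "cluster", "epoch": epoch,
                    "l1": float(np.mean(l1s)), "l4": float(np.mean(l4s)),
                    "label_change": float(change) if prev is not None else np.nan,
                    "lambda2": lambda2})

    z_all = full_latent(net, data)
    z_unit = LatentCode(z_all).unit
    w = soft_assignments(z_unit, v.data, plan.sigma)
    labels = hard_labels(w)
    if checkpoint_dir:
        net.save(os.path.join(checkpoint_dir, "stage3_cluster.npz"))
    return PipelineResult(
        latent=LatentCode(z_all),
        clusters=ClusterModel(v=v.data.copy(), w=w, sigma=plan.sigma, k=k),
        cluster_labels=labels, log=pd.DataFrame(log), network=net,
        lambda1=lambda1, lambda2=lambda2)
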