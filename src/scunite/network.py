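"""Batch-conditional ZINB denoising autoencoder.

The encoder consumes the z-scored expression matrix concatenated with the
one-hot batch indicator, so batch identity acts as a covariate the network
can regress out. The decoder mirrors the encoder, consumes [z || batch] and
feeds three output heads: dropout probability pi (logistic), mean mu
(exponential, scaled by the per-cell size factor) and inverse-dispersion
theta (softplus). A softmax classification head over the source cell types
is attached to the bottleneck.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from .zinb import PARAM_MIN, PARAM_MAX, PI_EPS, ZINBParams


@dataclass
class NetworkConfig:
    """Architecture and optimization knobs.

    Defaults follow the reference training recipe: encoder layers 256/64,
    a 32-dimensional bottleneck, minibatches of 256 cells, Adam at 1e-4,
    500 pretraining epochs and 100 fusion epochs.
    """

    encoder_sizes: tuple = (256, 64)
    d_latent: int = 32
    minibatch: int = 256
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    epochs_pretrain: int = 500
    epochs_fuse: int = 100
    epochs_cluster: int = 200
    seed: int = 0
    use_size_factor: bool = True
    grad_clip_norm: float = 5.0
    dtype: str = "float32"    # network/training precision
    denoise_sd: float = 1.0   # Gaussian input corruption during pretraining
    # Batch-normalize the trunk layers and the bottleneck. Centering the
    # latent is what lets pairwise cosine similarities spread over [-1, 1],
    # the regime the fusion thresholds (0.95 down to 0.5, lower band at
    # ~0.455) are designed for; without it a ReLU trunk yields a narrow
    # positive cone and the late fusion epochs merge unrelated cells.
    batchnorm: bool = True
    bn_momentum: float = 0.9

    def __post_init__(self):
        self.encoder_sizes = tuple(int(s) for s in self.encoder_sizes)
        if any(s <= 0 for s in self.encoder_sizes) or self.d_latent <= 0 \
                or self.minibatch <= 0:
            raise ValueError("all sizes must be positive")


@dataclass
class LatentCode:
    """Bottleneck representation of cells (cells x d_latent)."""

    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latent code contains non-finite entries")

    @property
    def d_latent(self) -> int:
        return self.z.shape[1]

    @property
    def unit(self) -> np.ndarray:
        """Row-normalized view used wherever cosine/sphere geometry applies."""
        norm = np.linalg.norm(self.z, axis=1, keepdims=True)
        return self.z / np.maximum(norm, 1e-12)


class ZINBAutoencoder:
    """The network. Weights are Glorot-uniform initialized from the seed."""

    def __init__(self, n_genes: int, n_batches: int, n_types: int,
                 config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        self.n_genes = int(n_genes)
        self.n_batches = int(n_batches)
        self.n_types = int(n_types)
        rng = np.random.default_rng(self.config.seed)
        e1, e2 = self.config.encoder_sizes
        d = self.config.d_latent
        self.dtype = np.dtype(self.config.dtype)
        self.weights: dict[str, ad.Tensor] = {}

        self.bn_stats: dict[str, np.ndarray] = {}

        def lin(name, fan_in, fan_out, bn=False):
            self.weights[f"{name}_W"] = ad.Tensor(
                ad.glorot_uniform(rng, fan_in, fan_out).astype(self.dtype),
                requires_grad=True)
            self.weights[f"{name}_b"] = ad.Tensor(
                np.zeros(fan_out, dtype=self.dtype), requires_grad=True)
            if bn and self.config.batchnorm:
                self.weights[f"{name}_g"] = ad.Tensor(
                    np.ones(fan_out, dtype=self.dtype), requires_grad=True)
                self.weights[f"{name}_beta"] = ad.Tensor(
                    np.zeros(fan_out, dtype=self.dtype), requires_grad=True)
                self.bn_stats[f"{name}_mean"] = np.zeros(fan_out,
                                                         dtype=self.dtype)
                self.bn_stats[f"{name}_var"] = np.ones(fan_out,
                                                       dtype=self.dtype)

        lin("enc1", self.n_genes + self.n_batches, e1, bn=True)
        lin("enc2", e1, e2, bn=True)
        lin("latent", e2, d, bn=True)
        lin("dec1", d + self.n_batches, e2, bn=True)
        lin("dec2", e2, e1, bn=True)
        lin("pi", e1, self.n_genes)
        lin("mu", e1, self.n_genes)
        lin("theta", e1, self.n_genes)
        lin("cls", d, self.n_types)

    # ------------------------------------------------------------------
    def parameters(self) -> list[ad.Tensor]:
        return list(self.weights.values())

    def _affine(self, name: str, x: ad.Tensor) -> ad.Tensor:
        return x @ self.weights[f"{name}_W"] + self.weights[f"{name}_b"]

    def _bn(self, name: str, t: ad.Tensor, training: bool,
            eps: float = 1e-5) -> ad.Tensor:
        """Batch normalization with running statistics for inference."""
        if not self.config.batchnorm:
            return t
        gamma = self.weights[f"{name}_g"]
        beta = self.weights[f"{name}_beta"]
        if training and t.shape[0] > 1:
            mu = t.mean(axis=0, keepdims=True)
            centered = t - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered / ad.sqrt(var + eps)
            m = self.config.bn_momentum
            self.bn_stats[f"{name}_mean"] = (
                m * self.bn_stats[f"{name}_mean"] + (1 - m) * mu.data.ravel()
            ).astype(self.dtype)
            self.bn_stats[f"{name}_var"] = (
                m * self.bn_stats[f"{name}_var"] + (1 - m) * var.data.ravel()
            ).astype(self.dtype)
        else:
            rm = self.bn_stats[f"{name}_mean"]
            rv = self.bn_stats[f"{name}_var"]
            xhat = (t - rm) / np.sqrt(rv + eps)
        return xhat * gamma + beta

    def _bn_eval_np(self, name: str, x: np.ndarray,
                    eps: float = 1e-5) -> np.ndarray:
        if not self.config.batchnorm:
            return x
        xhat = (x - self.bn_stats[f"{name}_mean"]) / np.sqrt(
            self.bn_stats[f"{name}_var"] + eps)
        return xhat * self.weights[f"{name}_g"].data \
            + self.weights[f"{name}_beta"].data

    def forward(self, x_input: np.ndarray, batch_onehot: np.ndarray,
                size_factor: np.ndarray,
                training: bool = False) -> dict[str, ad.Tensor]:
        """One differentiable pass; returns tensors keyed z/pi/mu/theta/log_probs."""
        x = np.asarray(x_input, dtype=self.dtype)
        b = np.asarray(batch_onehot, dtype=self.dtype)
        if x.shape[1] != self.n_genes or b.shape[1] != self.n_batches:
            raise ValueError("input width does not match the initialized network")
        sf = np.asarray(size_factor, dtype=self.dtype).reshape(-1, 1)

        enc_in = ad.Tensor(np.concatenate([x, b], axis=1))
        h = ad.relu(self._bn("enc1", self._affine("enc1", enc_in), training))
        h = ad.relu(self._bn("enc2", self._affine("enc2", h), training))
        z = self._bn("latent", self._affine("latent", h), training)

        dec_in = ad.concat([z, ad.Tensor(b)], axis=1)
        d = ad.relu(self._bn("dec1", self._affine("dec1", dec_in), training))
        d = ad.relu(self._bn("dec2", self._affine("dec2", d), training))

        pi = ad.clip(ad.sigmoid(self._affine("pi", d)), PI_EPS, 1.0 - PI_EPS)
        # pre-clip the log-mean so exp stays finite; clamp bounds make it lossless
        mu_lin = ad.clip(self._affine("mu", d), -30.0, 30.0)
        mu = ad.exp(mu_lin)
        if self.config.use_size_factor:
            mu = mu * sf
        mu = ad.clip(mu, PARAM_MIN, PARAM_MAX)
        theta = ad.clip(ad.softplus(self._affine("theta", d)), PARAM_MIN, PARAM_MAX)
        log_probs = ad.log_softmax(self._affine("cls", z), axis=1)
        return {"z": z, "pi": pi, "mu": mu, "theta": theta,
                "log_probs": log_probs}

    # -- no-grad conveniences -------------------------------------------
    def encode(self, x_input, batch_onehot) -> np.ndarray:
        """Inference-mode latent codes (running batch-norm statistics)."""
        x = np.asarray(x_input, dtype=self.dtype)
        b = np.asarray(batch_onehot, dtype=self.dtype)
        h = np.concatenate([x, b], axis=1) @ self.weights["enc1_W"].data \
            + self.weights["enc1_b"].data
        h = np.maximum(self._bn_eval_np("enc1", h), 0.0)
        h = np.maximum(self._bn_eval_np(
            "enc2", h @ self.weights["enc2_W"].data
            + self.weights["enc2_b"].data), 0.0)
        z = h @ self.weights["latent_W"].data + self.weights["latent_b"].data
        return self._bn_eval_np("latent", z)

    def predict(self, x_input, batch_onehot, size_factor):
        """Non-differentiable forward: (LatentCode, ZINBParams, class_probs)."""
        out = self.forward(x_input, batch_onehot, size_factor)
        return (LatentCode(out["z"].data),
                ZINBParams(out["pi"].data, out["mu"].data, out["theta"].data),
                np.exp(out["log_probs"].data))

    # -- checkpointing ---------------------------------------------------
    def save(self, path):
        meta = dict(asdict(self.config))
        meta.update(n_genes=self.n_genes, n_batches=self.n_batches,
                    n_types=self.n_types)
        arrays = {k: t.data for k, t in self.weights.items()}
        arrays.update({f"bnstat_{k}": v for k, v in self.bn_stats.items()})
        np.savez(path, _meta=np.frombuffer(
            json.dumps(meta, default=list).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ZINBAutoencoder":
        with np.load(path) as f:
            meta = json.loads(bytes(f["_meta"]).decode())
            arrays = {k: f[k] for k in f.files if k != "_meta"}
        cfg = NetworkConfig(**{k: meta[k] for k in NetworkConfig.__dataclass_fields__})
        net = cls(meta["n_genes"], meta["n_batches"], meta["n_types"], cfg)
        for k, arr in arrays.items():
            if k.startswith("bnstat_"):
                net.bn_stats[k[len("bnstat_"):]] = arr.astype(net.dtype,
                                                              copy=False)
            else:
                net.weights[k].data = arr.astype(net.dtype, copy=False)
        return net
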