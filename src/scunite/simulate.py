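"""Two-batch scRNA-seq count simulator (Splat-style generative model).

Counts are drawn hierarchically: gene base means from a Gamma; per-group
multiplicative differential-expression (DE) factors for a random subset of
genes; per-batch multiplicative gene factors; log-normal expected library
sizes; NB counts via a Poisson-Gamma mixture with a common biological
coefficient of variation; and mean-dependent logistic dropout whose
midpoint ``dropout_mid`` tunes the technical-zero rate (larger midpoint =
more zeros). The two batches share genes, groups and DE factors but get
independent batch factors and cells, emulating a labeled reference dataset
and an unlabeled query dataset of the same tissue.

The study grid crosses dataset size {equal, unequal}, group balance
{balanced, imbalanced (geometric ratio 0.8)} and dropout_mid
{-1, -0.5, 0, 0.5} — 16 scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from itertools import product

import numpy as np
from scipy.special import expit

from .data_io import CountMatrix

DROPOUT_MIDS = (-1.0, -0.5, 0.0, 0.5)


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the study's printed settings
    where given, Splat's published defaults otherwise."""

    n_genes: int = 2500
    n_groups: int = 6
    source_cells: int = 3600
    target_cells: int = 3600          # 1800 for the "unequal" setting
    balance: str = "balanced"         # or "imbalanced" (geometric ratio 0.8)
    imbalance_ratio: float = 0.8
    dropout_mid: float = 0.0
    dropout_shape: float = -1.0
    de_facscale: float = 0.2
    de_facloc: float = 0.1            # Splat default
    de_prob: float = 0.1              # Splat default
    # Between-batch expression factors default to "off": the study's
    # simulated source/target pair shows no substantive between-batch shift
    # (batch-naive centroid matching succeeds on it), so the two batches
    # differ only in their cells. Set loc/scale > 0 for explicit batch
    # effects (Splat's own defaults are 0.1/0.1).
    batch_facloc: float = 0.0
    batch_facscale: float = 0.0
    mean_shape: float = 0.6           # Splat default
    mean_rate: float = 0.3            # Splat default
    lib_loc: float = 11.0             # Splat default
    lib_scale: float = 0.2            # Splat default
    bcv: float = 0.2
    dropout: bool = True
    seed: int = 0

    def group_sizes(self, n_cells: int) -> np.ndarray:
        """Cells per group; imbalanced sizes follow a geometric sequence."""
        if self.balance == "balanced":
            p = np.full(self.n_groups, 1.0 / self.n_groups)
        elif self.balance == "imbalanced":
            p = self.imbalance_ratio ** np.arange(self.n_groups)
            p = p / p.sum()
        else:
            raise ValueError(f"unknown balance {self.balance!r}")
        sizes = np.floor(p * n_cells).astype(int)
        # largest-remainder rounding so sizes sum exactly to n_cells
        rem = p * n_cells - sizes
        for i in np.argsort(-rem)[: n_cells - sizes.sum()]:
            sizes[i] += 1
        if (sizes <= 0).any():
            raise ValueError("a group received no cells; increase cell count")
        return sizes


def _lognormal_factors(rng, n, loc, scale, sel_prob=1.0):
    """Multiplicative factors exp(loc + scale*N), flipped to reciprocals
    with probability 1/2; non-selected genes keep factor 1."""
    fac = np.ones(n)
    sel = rng.random(n) < sel_prob
    raw = np.exp(loc + scale * rng.standard_normal(sel.sum()))
    down = rng.random(sel.sum()) < 0.5
    raw[down] = 1.0 / raw[down]
    fac[sel] = raw
    return fac


def _simulate_batch(rng, cfg: SimConfig, base_means, de_factors, batch_factors,
                    n_cells, prefix):
    sizes = cfg.group_sizes(n_cells)
    groups = np.repeat(np.arange(cfg.n_groups), sizes)
    lib = np.exp(rng.normal(cfg.lib_loc, cfg.lib_scale, size=n_cells))

    gene_means = base_means[None, :] * de_factors[groups] * batch_factors[None, :]
    props = gene_means / gene_means.sum(axis=1, keepdims=True)
    lam = props * lib[:, None]

    # NB via Poisson-Gamma with common BCV: theta = 1 / bcv^2
    theta = 1.0 / cfg.bcv ** 2
    shaped = rng.gamma(theta, lam / theta)
    counts = rng.poisson(shaped)

    if cfg.dropout:
        with np.errstate(divide="ignore"):
            p_drop = expit(cfg.dropout_shape * (np.log(lam) - cfg.dropout_mid))
        counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    # guard against all-zero cells (possible at extreme dropout)
    zero_rows = counts.sum(axis=1) == 0
    if zero_rows.any():
        top = np.argmax(lam[zero_rows], axis=1)
        counts[np.where(zero_rows)[0], top] = 1

    gene_names = np.array([f"g{j:04d}" for j in range(cfg.n_genes)], dtype=object)
    cell_ids = np.array([f"{prefix}{i:05d}" for i in range(n_cells)], dtype=object)
    labels = np.array([str(g) for g in groups], dtype=object)
    return counts, gene_names, cell_ids, labels


def simulate_two_batch(cfg: SimConfig) -> tuple[CountMatrix, CountMatrix]:
    """Generate a (source, target) pair of labeled count matrices.

    Both matrices carry true group labels; the target labels are intended
    to be held out for evaluation only.
    """
    rng = np.random.default_rng(cfg.seed)
    base = rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=cfg.n_genes)
    de = np.vstack([
        _lognormal_factors(rng, cfg.n_genes, cfg.de_facloc, cfg.de_facscale,
                           sel_prob=cfg.de_prob)
        for _ in range(cfg.n_groups)])
    batch_fac = [
        _lognormal_factors(rng, cfg.n_genes, cfg.batch_facloc, cfg.batch_facscale)
        for _ in range(2)]

    c0, genes, ids0, lab0 = _simulate_batch(
        rng, cfg, base, de, batch_fac[0], cfg.source_cells, "S")
    c1, _, ids1, lab1 = _simulate_batch(
        rng, cfg, base, de, batch_fac[1], cfg.target_cells, "T")
    source = CountMatrix(c0, genes, ids0, batch=np.zeros(len(ids0), int),
                         labels=lab0)
    target = CountMatrix(c1, genes, ids1, batch=np.ones(len(ids1), int),
                         labels=lab1)
    return source, target


def remove_types(cm: CountMatrix, types_to_drop) -> CountMatrix:
    """Drop all cells of the named types; the gene set is unchanged."""
    drop = {str(t) for t in types_to_drop}
    keep = np.array([l not in drop for l in cm.labels])
    if not keep.any():
        raise ValueError("removing these types would drop every cell")
    return CountMatrix(cm.counts[keep], cm.gene_names, cm.cell_ids[keep],
                       batch=cm.batch[keep], labels=cm.labels[keep])


def scenario_grid(base: SimConfig | None = None) -> list[SimConfig]:
    """The 16-scenario study grid: {equal, unequal} x {balanced, imbalanced}
    x dropout_mid in {-1, -0.5, 0, 0.5}."""
    base = base or SimConfig()
    grid = []
    for size, bal, mid in product(("equal", "unequal"),
                                  ("balanced", "imbalanced"), DROPOUT_MIDS):
        grid.append(replace(
            base,
            target_cells=base.source_cells if size == "equal"
            else base.source_cells // 2,
            balance=bal, dropout_mid=mid))
    return grid


def scenario_config(size: str, balance: str, dropout_mid: float,
                    base: SimConfig | None = None, seed: int = 0) -> SimConfig:
    """Convenience constructor for one named grid scenario."""
    base = base or SimConfig()
    if size not in ("equal", "unequal"):
        raise ValueError("size must be 'equal' or 'unequal'")
    return replace(base,
                   target_cells=base.source_cells if size == "equal"
                   else base.source_cells // 2,
                   balance=balance, dropout_mid=float(dropout_mid), seed=seed)
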