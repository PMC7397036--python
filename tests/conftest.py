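"""Shared fixtures: scaled-down study scenarios run once per session.

Pipeline-level tests draw from a small set of session-scoped runs so the
expensive training happens once per session. Scenario *conditions*
(generator parameters, dropout grid, deleted groups) follow the study
design; problem sizes and epoch counts are the package's own desk-scale
choices (see docs/methods.md). The two headline checks (parameter
recovery, novel-type discovery) run near study scale with the pretraining
step budget the method needs; the grid and ablation blocks run at
miniature sizes so that every check executes in one short session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

import scunite as su

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

K = 6
GRID_MIDS = (-1.0, -0.5, 0.0, 0.5)
GRID_SEEDS = (1, 2)

# near-study-scale conditions for the two headline checks
RECOVERY = dict(sim=dict(n_genes=2500, source_cells=1500, target_cells=1500),
                n_hvg=1000, plan=dict(epochs_pretrain=200, epochs_fuse=100,
                                      epochs_cluster=40))
NOVEL = dict(sim=dict(n_genes=2500, source_cells=1800, target_cells=1800),
             n_hvg=1000, plan=dict(epochs_pretrain=170, epochs_fuse=100,
                                   epochs_cluster=40))

# miniature conditions for the grid and ablation blocks
GRID = dict(sim=dict(n_genes=2500, source_cells=240, target_cells=240),
            n_hvg=400, plan=dict(epochs_pretrain=60, epochs_fuse=100,
                                 epochs_cluster=40))
ABLATION = dict(sim=dict(n_genes=1000, source_cells=240, target_cells=240),
                n_hvg=400, plan=dict(epochs_pretrain=60, epochs_fuse=100,
                                     epochs_cluster=40))


@dataclass
class ScenarioRun:
    """One end-to-end pipeline run with its evaluation."""

    ari: float
    accuracy: float
    cluster_labels: np.ndarray        # all cells, source then target
    predicted_types: np.ndarray       # all cells
    target_mask: np.ndarray
    target_truth: np.ndarray          # aligned to target cells
    source_types: set
    latent_unit: np.ndarray
    log: "object"


def run_scenario(dropout_mid: float, seed: int, conditions, drop_source=(),
                 use_supervised=True, use_selfsup=True,
                 use_cluster=True) -> ScenarioRun:
    cfg = su.SimConfig(dropout_mid=dropout_mid, seed=seed,
                       **conditions["sim"])
    source, target = su.simulate_two_batch(cfg)
    if drop_source:
        source = su.remove_types(source, drop_source)
    data = su.preprocess(su.merge_on_shared_genes(source, target),
                         n_hvg=conditions["n_hvg"])
    plan = su.TrainPlan(seed=seed, use_supervised=use_supervised,
                        use_selfsup=use_selfsup, use_cluster=use_cluster,
                        **conditions["plan"])
    res = su.run_pipeline(data, K, plan,
                          config=su.NetworkConfig(minibatch=64))
    labels = [data.label_names[li] if li >= 0 else None
              for li in data.label_index]
    ann = su.annotate_clusters(res.cluster_labels, labels)
    tmask = data.batch == 1
    truth = np.asarray(list(target.labels), dtype=object)
    source_types = set(data.label_names)
    return ScenarioRun(
        ari=su.adjusted_rand_index(res.cluster_labels[tmask], truth),
        accuracy=su.annotation_accuracy(ann.predicted_types[tmask], truth,
                                        source_types),
        cluster_labels=res.cluster_labels,
        predicted_types=ann.predicted_types,
        target_mask=tmask,
        target_truth=truth,
        source_types=source_types,
        latent_unit=res.latent.unit,
        log=res.log,
    )


@pytest.fixture(scope="session")
def easy_run():
    """Full pipeline on the easiest scenario, near study scale."""
    return run_scenario(-1.0, 1, RECOVERY)


@pytest.fixture(scope="session")
def novel_run():
    """Hard scenario with groups 0 and 1 deleted from the source."""
    return run_scenario(0.5, 1, NOVEL, drop_source=("0", "1"))


@pytest.fixture(scope="session")
def grid_runs():
    """Reduced study grid: (equal, balanced) x dropout_mid x 2 seeds."""
    return {(mid, seed): run_scenario(mid, seed, GRID)
            for mid in GRID_MIDS for seed in GRID_SEEDS}


@pytest.fixture(scope="session")
def full_runs():
    """Full-model easy-scenario runs at the miniature ablation scale."""
    return {s: run_scenario(-1.0, s, ABLATION) for s in (1, 2, 3)}


@pytest.fixture(scope="session")
def ablation_runs():
    """Ablated runs (supervision off / self-supervision off), three seeds."""
    return {(flag, seed): run_scenario(-1.0, seed, ABLATION,
                                       **{flag: False})
            for flag in ("use_supervised", "use_selfsup")
            for seed in (1, 2, 3)}
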