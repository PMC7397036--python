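"""Evaluation indices: adjusted Rand index and annotation accuracy.

ARI is the chance-corrected pair-counting agreement between the clustering
and the true cell types, computed on target cells. Annotation accuracy is
the fraction of target cells — restricted to cell types shared with the
source — whose predicted type equals the true type; "unassigned" counts as
an error on this restricted set (penalizing false novelty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score


@dataclass
class EvalReport:
    ari: float
    annotation_accuracy: float
    n_overlap_cells: int


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    a = np.asarray(list(a))
    b = np.asarray(list(b))
    if len(a) != len(b):
        raise ValueError("partitions have different lengths")
    if len(a) < 2:
        raise ValueError("need at least two cells")
    return float(adjusted_rand_score(a, b))


def annotation_accuracy(pred, truth, source_types) -> float:
    """Accuracy over target cells whose true type exists in the source.

    Returns ``nan`` when no target cell's true type overlaps the source.
    """
    pred = np.asarray(list(pred), dtype=object)
    truth = np.asarray(list(truth), dtype=object)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth vectors are misaligned")
    keep = np.array([t in set(source_types) for t in truth])
    if not keep.any():
        return float("nan")
    return float(np.mean(pred[keep] == truth[keep]))


def evaluate(cluster_labels, pred_types, true_types, source_types) -> EvalReport:
    """Build the report for target cells.

    All vectors are aligned to target cells only.
    """
    truth = np.asarray(list(true_types), dtype=object)
    keep = np.array([t in set(source_types) for t in truth])
    return EvalReport(
        ari=adjusted_rand_index(cluster_labels, truth),
        annotation_accuracy=annotation_accuracy(pred_types, truth, source_types),
        n_overlap_cells=int(keep.sum()),
    )
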