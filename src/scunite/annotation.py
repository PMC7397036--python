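"""Clarity-score annotation of clusters over the source/target union.

For cluster i and source type c let f(i, c) be the fraction of all type-c
source cells that fall in cluster i. Types with f(i, c) > 0.5 are candidate
annotations (strictly greater; at most one cluster can capture more than
half of a type, so each type annotates at most one cluster). The cluster is
annotated with the candidate of largest f — its *clarity score* — or with
"unassigned" when no candidate exists, which is how novel cell types absent
from the reference surface. Target cells inherit their cluster's
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


@dataclass
class AnnotationResult:
    """Per-cluster and per-cell annotation tables."""

    clusters: pd.DataFrame   # cluster, annotated_type, clarity, n_cells, ...
    cells: pd.DataFrame      # cell position, cluster, predicted_type, is_source

    def cluster_type(self, cluster: int) -> str:
        row = self.clusters.loc[self.clusters["cluster"] == cluster]
        return row["annotated_type"].iloc[0]

    @property
    def predicted_types(self) -> np.ndarray:
        return self.cells["predicted_type"].to_numpy(object)


def annotate_clusters(cluster_labels, labels, k: int | None = None
                      ) -> AnnotationResult:
    """Annotate clusters from the composition of labeled source cells.

    Parameters
    ----------
    cluster_labels
        Integer cluster id per cell of the union.
    labels
        Per-cell type string, ``None`` for unlabeled (target) cells; must be
        aligned with ``cluster_labels``.
    k
        Optional expected number of clusters; an id in ``0..k-1`` with no
        cells raises an error.
    """
    cl = np.asarray(cluster_labels, dtype=int)
    lab = np.asarray(list(labels), dtype=object)
    if len(cl) != len(lab):
        raise ValueError("cluster labels and type labels are misaligned")
    is_source = np.array([x is not None for x in lab])
    if not is_source.any():
        raise ValueError("no labeled source cells to annotate from")

    present = np.unique(cl)
    if k is not None:
        empty = sorted(set(range(k)) - set(present.tolist()))
        if empty:
            raise ValueError(f"cluster(s) {empty} contain no cells")

    types = sorted({x for x in lab[is_source]})
    totals = {c: int(np.sum(lab[is_source] == c)) for c in types}

    rows = []
    cluster_to_type: dict[int, str] = {}
    for i in present:
        in_i = cl == i
        frac = {c: np.sum((lab == c) & in_i & is_source) / totals[c]
                for c in types}
        candidates = {c: f for c, f in frac.items() if f > 0.5}
        if candidates:
            best = max(candidates, key=lambda c: (candidates[c], ))
            # ties -> lexicographically smallest type name
            top = max(candidates.values())
            best = min(c for c, f in candidates.items() if f == top)
            ann, clarity = best, float(top)
        else:
            ann, clarity = UNASSIGNED, np.nan
        cluster_to_type[int(i)] = ann
        rows.append({
            "cluster": int(i), "annotated_type": ann, "clarity": clarity,
            "n_cells": int(in_i.sum()),
            "n_source": int((in_i & is_source).sum()),
            "n_target": int((in_i & ~is_source).sum()),
            "source_composition": ";".join(
                f"{c}:{frac[c]:.4f}" for c in types if frac[c] > 0),
        })

    cells = pd.DataFrame({
        "cluster": cl,
        "predicted_type": [cluster_to_type[int(i)] for i in cl],
        "is_source": is_source,
    })
    return AnnotationResult(clusters=pd.DataFrame(rows), cells=cells)
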