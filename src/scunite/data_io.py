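"""Reading, merging and preprocessing raw count matrices.

The network consumes a z-scored, log-normalized expression matrix restricted
to highly variable genes (HVGs); the ZINB likelihood is evaluated on the raw
counts of the same genes. Preprocessing follows the standard scRNA-seq
recipe, in order:

1. library-size normalization with target sum = median of per-cell totals
   (the per-cell scaling is kept as the ``size_factor``),
2. natural ``ln(1 + x)`` transform,
3. selection of the top ``n_hvg`` genes by normalized dispersion
   (variance/mean of the log data, z-scored within 20 equal-count mean
   bins),
4. per-gene z-scoring of the selected genes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw integer counts (cells x genes) with names, batch and labels.

    ``batch`` is a per-cell categorical index (0 = source, 1 = target by
    convention; more than two batches are allowed). ``labels`` holds the
    per-cell type string or ``None`` where unknown.
    """

    counts: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    batch: np.ndarray = None
    labels: np.ndarray = None

    def __post_init__(self):
        self.counts = _validate_counts(np.asarray(self.counts))
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n, m = self.counts.shape
        if len(self.gene_names) != m:
            raise ValueError("gene_names length does not match count columns")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match count rows")
        for names, what in ((self.gene_names, "gene names"),
                            (self.cell_ids, "cell ids")):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicated {what}")
        if self.batch is None:
            self.batch = np.zeros(n, dtype=int)
        self.batch = np.asarray(self.batch, dtype=int)
        if self.labels is None:
            self.labels = np.full(n, None, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.batch) != n or len(self.labels) != n:
            raise ValueError("batch/labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class ProcessedData:
    """Network-ready data: z-scored HVG input paired with its raw counts."""

    x_input: np.ndarray
    x_raw: np.ndarray
    size_factor: np.ndarray
    batch_onehot: np.ndarray
    hvg_names: np.ndarray
    label_index: np.ndarray          # -1 where the cell is unlabeled
    n_source_types: int
    label_names: list = field(default_factory=list)
    cell_ids: np.ndarray = None
    batch: np.ndarray = None
    labels: np.ndarray = None        # original strings, for evaluation only
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.x_input.shape[0]

    @property
    def n_hvg(self) -> int:
        return self.x_input.shape[1]

    @property
    def n_batches(self) -> int:
        return self.batch_onehot.shape[1]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _validate_counts(arr) -> np.ndarray:
    if sparse.issparse(arr):
        arr = arr.toarray()
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite entries in count matrix")
    if (arr < 0).any():
        raise ValueError("negative count")
    rounded = np.rint(arr)
    if np.abs(arr - rounded).max(initial=0.0) > 1e-6:
        raise ValueError("non-integer counts")
    return rounded.astype(np.int64)


def read_counts(path, fmt: str = "dense_csv", genes_file=None, cells_file=None,
                cells_in_columns: bool = True, sep: str = ",") -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        Dense delimited file (cells in rows, gene-name header, first column
        cell ids) or a MatrixMarket ``.mtx`` file.
    fmt
        ``"dense_csv"`` or ``"mtx"``.
    genes_file, cells_file
        Sidecar one-name-per-line files for ``mtx`` input. Default to
        ``genes.tsv`` / ``barcodes.tsv`` next to the matrix.
    cells_in_columns
        MTX orientation flag; the CellRanger convention stores genes as rows
        and cells as columns.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "dense_csv":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(df.to_numpy(), df.columns.to_numpy(object),
                           df.index.astype(str).to_numpy(object))
    if fmt == "mtx":
        folder = os.path.dirname(os.path.abspath(path))
        genes_file = genes_file or os.path.join(folder, "genes.tsv")
        cells_file = cells_file or os.path.join(folder, "barcodes.tsv")
        for f in (genes_file, cells_file):
            if not os.path.exists(f):
                raise FileNotFoundError(f)
        mat = spio.mmread(path)
        genes = pd.read_csv(genes_file, header=None, sep="\t")[0].to_numpy(object)
        cells = pd.read_csv(cells_file, header=None, sep="\t")[0].to_numpy(object)
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if cells_in_columns:
            mat = mat.T
        return CountMatrix(mat, genes, cells)
    raise ValueError(f"unknown format {fmt!r}")


def read_metadata(path) -> pd.DataFrame:
    """TSV with columns cell_id, batch, label (label may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "label": str})
    required = {"cell_id", "batch"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    if "label" not in df.columns:
        df["label"] = None
    df["label"] = df["label"].where(pd.notna(df["label"]), None)
    return df


def apply_metadata(cm: CountMatrix, meta: pd.DataFrame) -> CountMatrix:
    """Attach batch/label columns from a metadata table by cell id."""
    meta = meta.set_index("cell_id")
    missing = [c for c in cm.cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} cells missing from metadata, e.g. {missing[0]!r}")
    sub = meta.loc[list(cm.cell_ids)]
    labels = np.array([l if (l is not None and l == l and l != "") else None
                       for l in sub["label"]], dtype=object)
    return CountMatrix(cm.counts, cm.gene_names, cm.cell_ids,
                       batch=sub["batch"].to_numpy(int), labels=labels)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_on_shared_genes(source: CountMatrix, target: CountMatrix) -> CountMatrix:
    """Stack source and target cells on the intersection of gene names.

    Genes keep the source ordering; batch is 0 for source rows and 1 for
    target rows. Source labels are carried over; target labels are dropped
    (they are evaluation-only and handled separately).
    """
    target_set = set(target.gene_names)
    shared = [g for g in source.gene_names if g in target_set]
    if not shared:
        raise ValueError("empty gene intersection between source and target")
    src_idx = [i for i, g in enumerate(source.gene_names) if g in set(shared)]
    tgt_pos = {g: i for i, g in enumerate(target.gene_names)}
    tgt_idx = [tgt_pos[g] for g in shared]

    counts = np.vstack([source.counts[:, src_idx], target.counts[:, tgt_idx]])
    cell_ids = np.concatenate([source.cell_ids, target.cell_ids])
    if len(set(cell_ids)) != len(cell_ids):
        cell_ids = np.array(
            [f"{c}-0" for c in source.cell_ids] + [f"{c}-1" for c in target.cell_ids],
            dtype=object)
    batch = np.concatenate([np.zeros(source.n_cells, int),
                            np.ones(target.n_cells, int)])
    labels = np.concatenate([source.labels,
                             np.full(target.n_cells, None, dtype=object)])
    return CountMatrix(counts, np.asarray(shared, dtype=object), cell_ids,
                       batch=batch, labels=labels)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _normalized_dispersion(logx: np.ndarray, n_bins: int) -> np.ndarray:
    """Dispersion (var/mean) of the log data, z-scored in equal-count mean bins."""
    mean = logx.mean(axis=0)
    var = logx.var(axis=0, ddof=1) if logx.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.argsort(mean, kind="stable")
    nd = np.zeros_like(disp)
    for chunk in np.array_split(order, min(n_bins, len(order))):
        if len(chunk) == 0:
            continue
        d = disp[chunk]
        s = d.std(ddof=1) if len(chunk) > 1 else 0.0
        nd[chunk] = (d - d.mean()) / s if s > 0 else 0.0
    return nd


def preprocess(cm: CountMatrix, n_hvg: int = 1000, n_bins: int = 20,
               clip: float | None = None) -> ProcessedData:
    """Run the four-step preprocessing pipeline (see module docstring).

    Deterministic: dispersion ties are broken by ascending gene index. If
    the matrix holds fewer than ``n_hvg`` genes, all genes are kept. The
    z-score is unclipped unless ``clip`` is given.
    """
    if cm.n_cells == 0 or cm.n_genes == 0:
        raise ValueError("empty count matrix")
    totals = cm.counts.sum(axis=1).astype(float)
    if (totals <= 0).any():
        bad = cm.cell_ids[totals <= 0][0]
        raise ValueError(f"cell with zero total count: {bad!r}")
    size_factor = totals / np.median(totals)
    logx = np.log1p(cm.counts / size_factor[:, None])

    nd = _normalized_dispersion(logx, n_bins)
    k = min(int(n_hvg), cm.n_genes)
    ranked = sorted(range(cm.n_genes), key=lambda j: (-nd[j], j))
    selected = np.array(sorted(ranked[:k]), dtype=int)  # keep input gene order

    sub = logx[:, selected]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    x_input = (sub - mu) / np.where(sd > 0, sd, 1.0)
    if clip is not None:
        x_input = np.clip(x_input, -clip, clip)

    batches = np.unique(cm.batch)
    onehot = (cm.batch[:, None] == batches[None, :]).astype(float)

    label_names = sorted({l for l in cm.labels if l is not None})
    lut = {l: i for i, l in enumerate(label_names)}
    label_index = np.array([lut.get(l, -1) for l in cm.labels], dtype=int)

    return ProcessedData(
        x_input=x_input,
        x_raw=cm.counts[:, selected],
        size_factor=size_factor,
        batch_onehot=onehot,
        hvg_names=cm.gene_names[selected],
        label_index=label_index,
        n_source_types=len(label_names),
        label_names=label_names,
        cell_ids=cm.cell_ids,
        batch=cm.batch.copy(),
        labels=cm.labels.copy(),
        params={"n_hvg": int(n_hvg), "n_bins": int(n_bins), "clip": clip},
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_processed(data: ProcessedData, out_dir) -> None:
    """Persist a ProcessedData as a directory of delimited files + manifest."""
    os.makedirs(out_dir, exist_ok=True)
    idx = pd.Index(data.cell_ids, name="cell_id")
    pd.DataFrame(data.x_input, index=idx, columns=data.hvg_names).to_csv(
        os.path.join(out_dir, "x_input.tsv"), sep="\t")
    pd.DataFrame(data.x_raw, index=idx, columns=data.hvg_names).to_csv(
        os.path.join(out_dir, "x_raw.tsv"), sep="\t")
    cells = pd.DataFrame({
        "cell_id": data.cell_ids, "batch": data.batch,
        "size_factor": data.size_factor, "label_index": data.label_index,
        "label": [l if l is not None else "" for l in data.labels]})
    cells.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)
    manifest = {"n_source_types": data.n_source_types,
                "label_names": list(data.label_names),
                "params": data.params}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_processed(out_dir) -> ProcessedData:
    xi = pd.read_csv(os.path.join(out_dir, "x_input.tsv"), sep="\t", index_col=0)
    xr = pd.read_csv(os.path.join(out_dir, "x_raw.tsv"), sep="\t", index_col=0)
    cells = pd.read_csv(os.path.join(out_dir, "cells.tsv"), sep="\t")
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    batch = cells["batch"].to_numpy(int)
    batches = np.unique(batch)
    labels = np.array([l if isinstance(l, str) and l != "" else None
                       for l in cells["label"].fillna("")], dtype=object)
    return ProcessedData(
        x_input=xi.to_numpy(float), x_raw=xr.to_numpy(int),
        size_factor=cells["size_factor"].to_numpy(float),
        batch_onehot=(batch[:, None] == batches[None, :]).astype(float),
        hvg_names=xi.columns.to_numpy(object),
        label_index=cells["label_index"].to_numpy(int),
        n_source_types=manifest["n_source_types"],
        label_names=manifest["label_names"],
        cell_ids=cells["cell_id"].to_numpy(object),
        batch=batch, labels=labels, params=manifest["params"])
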