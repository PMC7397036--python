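"""Reading, merging and the preprocessing pipeline."""

import numpy as np
import pandas as pd
import pytest

from scunite.data_io import (CountMatrix, merge_on_shared_genes, preprocess,
                             read_counts, save_processed, load_processed)


@pytest.fixture()
def tiny_csv(tmp_path):
    path = tmp_path / "counts.csv"
    path.write_text("cell,g1,g2\nc1,0,5\nc2,1,0\nc3,2,2\n")
    return path


def write_mtx(tmp_path, counts, genes, cells):
    """Write counts (cells x genes) in CellRanger orientation (genes x cells)."""
    from scipy import io as spio, sparse
    spio.mmwrite(str(tmp_path / "matrix.mtx"), sparse.coo_matrix(counts.T))
    (tmp_path / "genes.tsv").write_text("\n".join(genes) + "\n")
    (tmp_path / "barcodes.tsv").write_text("\n".join(cells) + "\n")
    return tmp_path / "matrix.mtx"


class TestReadCounts:
    def test_dense_csv_identity(self, tiny_csv):
        cm = read_counts(tiny_csv)
        np.testing.assert_array_equal(cm.counts, [[0, 5], [1, 0], [2, 2]])
        assert list(cm.gene_names) == ["g1", "g2"]
        assert list(cm.cell_ids) == ["c1", "c2", "c3"]

    def test_mtx_roundtrip_matches_dense(self, tiny_csv, tmp_path):
        dense = read_counts(tiny_csv)
        mtx = write_mtx(tmp_path, dense.counts, dense.gene_names, dense.cell_ids)
        cm = read_counts(mtx, fmt="mtx")
        np.testing.assert_array_equal(cm.counts, dense.counts)
        assert list(cm.gene_names) == list(dense.gene_names)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("cell,g1\nc1,-1\n")
        with pytest.raises(ValueError, match="negative count"):
            read_counts(path)

    def test_non_integer_rejected_but_near_integer_rounded(self, tmp_path):
        ok = tmp_path / "ok.csv"
        ok.write_text("cell,g1\nc1,2.0000001\n")
        assert read_counts(ok).counts[0, 0] == 2
        bad = tmp_path / "bad.csv"
        bad.write_text("cell,g1\nc1,2.5\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_counts(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_counts(tmp_path / "nope.csv")

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            CountMatrix([[1, 2]], ["g", "g"], ["c1"])


class TestMerge:
    def make(self, genes, n_cells=2, prefix="c", seed=0):
        rng = np.random.default_rng(seed)
        return CountMatrix(rng.integers(0, 9, (n_cells, len(genes))),
                           list(genes),
                           [f"{prefix}{i}" for i in range(n_cells)])

    def test_intersection_in_source_order(self):
        src = self.make("abc", prefix="s")
        tgt = self.make("bcd", prefix="t")
        merged = merge_on_shared_genes(src, tgt)
        assert list(merged.gene_names) == ["b", "c"]
        assert merged.n_cells == 4
        np.testing.assert_array_equal(merged.batch, [0, 0, 1, 1])

    def test_identical_gene_sets(self):
        src = self.make("abc", prefix="s")
        tgt = self.make("abc", prefix="t", seed=1)
        merged = merge_on_shared_genes(src, tgt)
        assert list(merged.gene_names) == ["a", "b", "c"]
        assert merged.n_cells == 4

    def test_disjoint_gene_sets_raise(self):
        with pytest.raises(ValueError, match="intersection"):
            merge_on_shared_genes(self.make("ab"), self.make("cd"))

    def test_target_gene_permutation_invariance(self):
        src = self.make("abcd", n_cells=3, prefix="s")
        perm = [2, 0, 3, 1]
        tgt = CountMatrix(src.counts[:, perm], src.gene_names[perm],
                          src.cell_ids)
        merged = merge_on_shared_genes(src, tgt)
        np.testing.assert_array_equal(merged.counts[3:], src.counts)

    def test_source_labels_carried_target_labels_dropped(self):
        src = self.make("ab", prefix="s")
        src.labels[:] = ["x", "y"]
        tgt = self.make("ab", prefix="t")
        tgt.labels[:] = ["x", "x"]
        merged = merge_on_shared_genes(src, tgt)
        assert list(merged.labels) == ["x", "y", None, None]


def brute_force_preprocess(counts, n_hvg, n_bins=20):
    """Loop-based reimplementation of the 4-step pipeline."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    sf = totals / np.median(totals)
    logx = np.log(1 + counts / sf[:, None])
    mean = logx.mean(axis=0)
    var = logx.var(axis=0, ddof=1)
    disp = np.array([v / m if m > 0 else 0.0 for m, v in zip(mean, var)])
    order = np.argsort(mean, kind="stable")
    nd = np.zeros_like(disp)
    for chunk in np.array_split(order, min(n_bins, len(order))):
        d = disp[chunk]
        s = d.std(ddof=1) if len(chunk) > 1 else 0.0
        nd[chunk] = (d - d.mean()) / s if s > 0 else 0.0
    ranked = sorted(range(counts.shape[1]), key=lambda j: (-nd[j], j))
    sel = sorted(ranked[:n_hvg])
    sub = logx[:, sel]
    sd = sub.std(axis=0)
    x = (sub - sub.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return sf, sel, x


class TestPreprocess:
    @pytest.fixture()
    def cm(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(2, 0.2, size=(30, 50))
        counts[:, 0] += 1  # ensure nonzero totals
        return CountMatrix(counts, [f"g{j}" for j in range(50)],
                           [f"c{i}" for i in range(30)],
                           batch=rng.integers(0, 2, 30))

    def test_columns_are_zscored(self, cm):
        data = preprocess(cm, n_hvg=20)
        np.testing.assert_allclose(data.x_input.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(data.x_input.var(axis=0), 1.0, atol=1e-6)

    def test_size_factors_from_median(self):
        counts = np.array([[50, 50], [150, 150]])
        cm = CountMatrix(counts, ["g1", "g2"], ["c1", "c2"])
        data = preprocess(cm, n_hvg=2)
        np.testing.assert_allclose(data.size_factor, [0.5, 1.5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 30, size=(5, 8))
        counts[:, 0] += 1
        cm = CountMatrix(counts, [f"g{j}" for j in range(8)],
                         [f"c{i}" for i in range(5)])
        data = preprocess(cm, n_hvg=4, n_bins=3)
        sf, sel, x = brute_force_preprocess(counts, 4, n_bins=3)
        np.testing.assert_allclose(data.size_factor, sf)
        assert [f"g{j}" for j in sel] == list(data.hvg_names)
        np.testing.assert_allclose(data.x_input, x, atol=1e-12)

    def test_all_genes_kept_when_n_hvg_equals_n_genes(self, cm):
        data = preprocess(cm, n_hvg=50)
        assert list(data.hvg_names) == [f"g{j}" for j in range(50)]

    def test_hvg_selection_then_zscore_equals_no_selection(self, cm):
        a = preprocess(cm, n_hvg=50)
        b = preprocess(cm, n_hvg=10_000)
        np.testing.assert_array_equal(a.x_input, b.x_input)

    def test_deterministic(self, cm):
        a = preprocess(cm, n_hvg=20)
        b = preprocess(cm, n_hvg=20)
        np.testing.assert_array_equal(a.x_input, b.x_input)
        assert list(a.hvg_names) == list(b.hvg_names)

    def test_zero_total_cell_rejected(self):
        cm = CountMatrix([[0, 0], [1, 2]], ["g1", "g2"], ["c1", "c2"])
        with pytest.raises(ValueError, match="zero total"):
            preprocess(cm)

    def test_batch_onehot_rows_sum_to_one(self, cm):
        data = preprocess(cm, n_hvg=10)
        np.testing.assert_array_equal(data.batch_onehot.sum(axis=1), 1.0)

    def test_x_raw_aligned_with_hvg_names(self, cm):
        data = preprocess(cm, n_hvg=15)
        name_to_col = {g: j for j, g in enumerate(cm.gene_names)}
        cols = [name_to_col[g] for g in data.hvg_names]
        np.testing.assert_array_equal(data.x_raw, cm.counts[:, cols])

    def test_save_load_roundtrip(self, cm, tmp_path):
        cm.labels[:15] = "typeA"
        data = preprocess(cm, n_hvg=12)
        save_processed(data, tmp_path / "proc")
        back = load_processed(tmp_path / "proc")
        np.testing.assert_allclose(back.x_input, data.x_input, atol=1e-12)
        np.testing.assert_array_equal(back.x_raw, data.x_raw)
        np.testing.assert_array_equal(back.label_index, data.label_index)
        assert back.n_source_types == data.n_source_types
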