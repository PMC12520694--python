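import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse as sp

import hypoxclass as hx
from hypoxclass.errors import ValidationError
from hypoxclass.formats_io import read_annotation, write_annotation, read_labels, write_labels


def _triplet_dir(tmp_path, matrix, gene_ids, cell_ids, genes_on_rows=True):
    d = tmp_path / "bundle"
    d.mkdir(parents=True)
    m = sp.coo_matrix(matrix if genes_on_rows else np.asarray(matrix).T)
    scipy.io.mmwrite(str(d / "matrix.mtx"), m, field="integer")
    (d / "features.tsv").write_text("\n".join(gene_ids) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(cell_ids) + "\n")
    return d


class TestCounts:
    def test_triplet_conservation(self, tmp_path):
        # 3 cells x 4 genes, 5 nonzeros: total count survives the round trip
        mat = np.zeros((4, 3), dtype=int)  # genes x cells
        vals = [3, 1, 4, 1, 5]
        for (i, j), v in zip([(0, 0), (1, 1), (2, 2), (3, 0), (0, 2)], vals):
            mat[i, j] = v
        d = _triplet_dir(tmp_path, mat, [f"g{i}" for i in range(4)], [f"c{i}" for i in range(3)])
        cm = hx.read_counts(d)
        assert cm.counts.shape == (3, 4)
        assert cm.total() == sum(vals)

    def test_roundtrip_exact(self, tmp_path, rng):
        mat = sp.csr_matrix(rng.integers(0, 5, size=(10, 20)))
        cm = hx.CountMatrix([f"c{i}" for i in range(10)], [f"g{i}" for i in range(20)], mat)
        hx.write_counts(cm, tmp_path / "out")
        back = hx.read_counts(tmp_path / "out")
        assert back.cell_ids == cm.cell_ids
        assert back.gene_ids == cm.gene_ids
        assert (back.counts != cm.counts).nnz == 0

    def test_orientation_autodetect(self, tmp_path, rng):
        # cells-on-rows triplet yields the same object when ids disambiguate
        mat = rng.integers(0, 4, size=(6, 9))  # genes x cells... here 6 genes, 9 cells
        genes = [f"g{i}" for i in range(6)]
        cells = [f"c{i}" for i in range(9)]
        d1 = _triplet_dir(tmp_path / "a", mat, genes, cells, genes_on_rows=True)
        d2 = _triplet_dir(tmp_path / "b", mat, genes, cells, genes_on_rows=False)
        cm1, cm2 = hx.read_counts(d1), hx.read_counts(d2)
        assert (cm1.counts != cm2.counts).nnz == 0
        assert cm1.cell_ids == cm2.cell_ids == cells

    def test_dimension_mismatch(self, tmp_path):
        d = _triplet_dir(tmp_path, np.ones((4, 4), dtype=int),
                         [f"g{i}" for i in range(4)], [f"c{i}" for i in range(3)])
        with pytest.raises(ValidationError, match="dimension mismatch"):
            hx.read_counts(d)

    @pytest.mark.parametrize("sep", [",", "\t"])
    def test_dense_table_delimiters(self, tmp_path, sep):
        p = tmp_path / "dense.txt"
        header = sep.join(["cell", "g1", "g2", "g3"])
        rows = [sep.join(["c1", "1", "0", "2"]), sep.join(["c2", "0", "3", "0"])]
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        cm = hx.read_counts(p, layout="dense_table")
        assert cm.cell_ids == ["c1", "c2"]
        assert cm.total() == 6

    @pytest.mark.parametrize("bad, msg", [
        (np.array([[1, -2], [0, 1]]), "negative"),
        (np.array([[1.5, 0], [0, 1]]), "non-integral"),
    ])
    def test_invalid_entries(self, bad, msg):
        with pytest.raises(ValidationError, match=msg):
            hx.CountMatrix(["c1", "c2"], ["g1", "g2"], sp.csr_matrix(bad))

    def test_duplicate_ids(self):
        with pytest.raises(ValidationError, match="duplicate cell ids"):
            hx.CountMatrix(["c1", "c1"], ["g1", "g2"], sp.csr_matrix(np.ones((2, 2))))


class TestGMT:
    def test_dedup_preserves_first(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("HYPOXIA_A\tdesc\tVEGFA\tSLC2A1\tVEGFA\n")
        gsc = hx.read_gmt(p)
        assert gsc.sets["HYPOXIA_A"] == ["VEGFA", "SLC2A1"]

    def test_no_genes_errors_with_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("ONLYNAME\tdesc\n")
        with pytest.raises(ValidationError, match="no genes on line 1"):
            hx.read_gmt(p)

    def test_seven_sets_ordered(self, tmp_path):
        p = tmp_path / "s.gmt"
        lines = [f"SET_{i}\td\tA{i}\tB{i}" for i in range(7)]
        p.write_text("\n".join(lines) + "\n\n")  # trailing empty line skipped
        gsc = hx.read_gmt(p)
        assert len(gsc) == 7
        assert gsc.names == [f"SET_{i}" for i in range(7)]

    def test_duplicate_set_name(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\td\tA\nS\td\tB\n")
        with pytest.raises(ValidationError, match="duplicate set name"):
            hx.read_gmt(p)

    def test_roundtrip(self, tmp_path):
        gsc = hx.GeneSetCollection({"A": ["x", "y"], "B": ["z"]}, {"A": "d1", "B": "d2"})
        hx.write_gmt(gsc, tmp_path / "o.gmt")
        back = hx.read_gmt(tmp_path / "o.gmt")
        assert back.sets == gsc.sets and back.descriptions == gsc.descriptions


class TestEmbedding:
    def _write(self, tmp_path, cells, d=8):
        p = tmp_path / "emb.tsv"
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(len(cells), d)),
                          index=pd.Index(cells, name="cell_id"))
        df.to_csv(p, sep="\t")
        return p, df

    def test_reordered_to_expected(self, tmp_path):
        p, df = self._write(tmp_path, ["C1", "C2", "C3", "C4"])
        emb = hx.read_embedding(p, ["C3", "C1", "C4", "C2"])
        assert emb.cell_ids == ["C3", "C1", "C4", "C2"]
        np.testing.assert_allclose(emb.matrix[0], df.loc["C3"].to_numpy())

    def test_missing_cell(self, tmp_path):
        p, _ = self._write(tmp_path, ["C1", "C2", "C4"])
        with pytest.raises(ValidationError, match="missing cells: C3"):
            hx.read_embedding(p, ["C1", "C2", "C3", "C4"])

    def test_non_finite(self, tmp_path):
        p, df = self._write(tmp_path, ["C1", "C2", "C3"])
        df.iloc[2, 5] = np.nan
        df.to_csv(p, sep="\t")
        with pytest.raises(ValidationError, match="non-finite value"):
            hx.read_embedding(p, ["C1", "C2", "C3"])


def test_annotation_and_labels_roundtrip(tmp_path):
    ann = hx.GeneAnnotation(pd.DataFrame(
        {"is_protein_coding": [True, False], "is_mitochondrial": [False, True]},
        index=pd.Index(["g1", "MT-g2"], name="gene_id")))
    write_annotation(ann, tmp_path / "ann.tsv")
    back = read_annotation(tmp_path / "ann.tsv")
    pd.testing.assert_frame_equal(back.table, ann.table)

    table = pd.DataFrame({"cell_id": ["a", "b"], "status": ["HC_HYPOXIC", "LOW_CONF"],
                          "group_S": ["HIGH", "LOW"], "posterior_S": [0.9, 0.2]})
    write_labels(table, tmp_path / "lab.tsv")
    back = read_labels(tmp_path / "lab.tsv")
    pd.testing.assert_frame_equal(back, table)
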