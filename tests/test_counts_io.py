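"""Count-matrix container invariants and MTX/bulk-table round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lagsc import CountMatrix, read_bulk_table, read_mtx_dir, read_mtx_triplet, write_mtx_triplet
from lagsc.counts_io import BulkProfile, write_bulk_table
from lagsc.exceptions import FormatError


def _write_triplet(tmp_path, header, entries, genes, barcodes):
    mtx = tmp_path / "matrix.mtx"
    lines = ["%%MatrixMarket matrix coordinate integer general", header]
    lines += [f"{i} {j} {v}" for i, j, v in entries]
    mtx.write_text("\n".join(lines) + "\n")
    (tmp_path / "features.tsv").write_text("".join(g + "\n" for g in genes))
    (tmp_path / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))
    return tmp_path


class TestReadMtx:
    def test_triplets_transcribed_to_dense(self, tmp_path):
        d = _write_triplet(tmp_path, "3 2 2", [(1, 1, 5), (3, 2, 2)],
                           ["g1", "g2", "g3"], ["b1", "b2"])
        cm = read_mtx_dir(d)
        assert cm.counts.tolist() == [[5, 0], [0, 0], [0, 2]]
        assert cm.gene_ids == ["g1", "g2", "g3"]
        assert cm.barcodes == ["b1", "b2"]

    def test_empty_coordinate_section_gives_zero_matrix(self, tmp_path):
        d = _write_triplet(tmp_path, "3 2 0", [], ["g1", "g2", "g3"], ["b1", "b2"])
        cm = read_mtx_dir(d)
        assert cm.counts.shape == (3, 2)
        assert cm.counts.sum() == 0

    def test_dimension_mismatch_rejected(self, tmp_path):
        d = _write_triplet(tmp_path, "3 2 1", [(1, 1, 5)], ["g1", "g2"], ["b1", "b2"])
        with pytest.raises(FormatError):
            read_mtx_dir(d)

    def test_negative_entry_rejected(self, tmp_path):
        d = _write_triplet(tmp_path, "3 2 1", [(1, 1, -5)],
                           ["g1", "g2", "g3"], ["b1", "b2"])
        with pytest.raises(FormatError):
            read_mtx_dir(d)

    def test_mito_prefix_rule(self, tmp_path):
        d = _write_triplet(tmp_path, "2 1 1", [(1, 1, 3)], ["Q0045", "YAL001C"], ["b1"])
        cm = read_mtx_dir(d)
        assert cm.mito_flags.tolist() == [True, False]


class TestWriteMtx:
    def test_single_entry_triplet_line(self, tmp_path):
        cm = CountMatrix(np.array([[7]]), ["g1"], ["b1"])
        paths = write_mtx_triplet(cm, tmp_path)
        body = [l for l in open(paths["matrix"]).read().splitlines()
                if not l.startswith("%")]
        assert body[0].split() == ["1", "1", "1"]  # header: 1x1, 1 entry
        assert body[1].split() == ["1", "1", "7"]

    def test_zero_matrix_has_empty_coordinate_section(self, tmp_path):
        cm = CountMatrix(np.zeros((3, 2), dtype=int), ["a", "b", "c"], ["x", "y"])
        paths = write_mtx_triplet(cm, tmp_path)
        body = [l for l in open(paths["matrix"]).read().splitlines()
                if not l.startswith("%")]
        assert body[0].split()[2] == "0"
        assert len(body) == 1


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    counts=arrays(np.int64, (6, 4), elements=st.integers(0, 50)),
)
def test_round_trip_is_identity(tmp_path_factory, counts):
    """read(write(cm)) reproduces matrix, ids, barcodes and total UMIs."""
    tmp = tmp_path_factory.mktemp("rt")
    cm = CountMatrix(counts, [f"g{i}" for i in range(6)], [f"b{i}" for i in range(4)])
    write_mtx_triplet(cm, tmp)
    back = read_mtx_dir(tmp)
    assert np.array_equal(back.counts, cm.counts)
    assert back.gene_ids == cm.gene_ids
    assert back.barcodes == cm.barcodes
    assert back.counts.sum() == cm.counts.sum()


class TestCountMatrixInvariants:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(FormatError):
            CountMatrix(np.zeros((2, 1), dtype=int), ["g", "g"], ["b"])

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(FormatError):
            CountMatrix(np.zeros((1, 2), dtype=int), ["g"], ["b", "b"])

    def test_negative_counts_rejected(self):
        with pytest.raises(FormatError):
            CountMatrix(np.array([[-1]]), ["g"], ["b"])

    def test_non_integral_counts_rejected(self):
        with pytest.raises(FormatError):
            CountMatrix(np.array([[1.5]]), ["g"], ["b"])


class TestBulkTable:
    def test_three_row_table(self, tmp_path):
        p = tmp_path / "bulk.tsv"
        p.write_text("g1\t1.5\ng2\t0\ng3\t20\n")
        bp = read_bulk_table(p)
        assert bp.gene_ids == ["g1", "g2", "g3"]
        assert bp.fpkm.tolist() == [1.5, 0.0, 20.0]

    def test_header_autodetected(self, tmp_path):
        p = tmp_path / "bulk.tsv"
        p.write_text("gene_id\tfpkm\ng1\t1.5\n")
        assert read_bulk_table(p).gene_ids == ["g1"]

    def test_negative_fpkm_rejected(self, tmp_path):
        p = tmp_path / "bulk.tsv"
        p.write_text("g1\t-1\n")
        with pytest.raises(ValueError):
            read_bulk_table(p)

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "bulk.tsv"
        p.write_text("g1\t1\ng1\t2\n")
        with pytest.raises(FormatError):
            read_bulk_table(p)

    def test_write_read_round_trip(self, tmp_path):
        bp = BulkProfile(["a", "b"], [0.0, 3.25])
        p = tmp_path / "bulk.tsv"
        write_bulk_table(bp, p)
        back = read_bulk_table(p)
        assert back.gene_ids == bp.gene_ids
        assert np.allclose(back.fpkm, bp.fpkm)
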