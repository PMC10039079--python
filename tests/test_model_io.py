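import io

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from barnyardqc import (
    CountMatrix,
    FormatError,
    LayoutError,
    ReadLayout,
    SynchronizationError,
    TranscriptCatalog,
    UNASSIGNED,
    make_feature_table,
    parse_fastq_pair,
    read_count_matrix,
    read_tagged_reads,
    write_count_matrix,
    write_tagged_reads,
)
from barnyardqc.model_io import ParseReport


class TestReadLayout:
    def test_defaults_follow_bead_design(self):
        layout = ReadLayout()
        assert (layout.r1_length, layout.r2_length) == (30, 70)
        assert layout.barcode_length == 16
        assert layout.umi_length == 12

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"barcode_span": (0, 16), "umi_span": (10, 22)},  # overlap
            {"barcode_span": (0, 40)},  # beyond R1
            {"umi_span": (16, 16)},  # zero length
        ],
    )
    def test_invalid_layouts_rejected(self, kwargs):
        with pytest.raises(LayoutError):
            ReadLayout(**kwargs)


class TestCountMatrixIO:
    def test_three_gene_two_barcode_parse(self, tmp_path, two_species_features):
        # entries {(1,1,5),(3,2,2)} in 1-based MTX coordinates
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 2\n1 1 5\n3 2 2\n"
        )
        (tmp_path / "features.tsv").write_text(
            "g1\thuman\tFalse\ng2\thuman\tFalse\ng3\thuman\tTrue\n"
        )
        (tmp_path / "barcodes.tsv").write_text("AAAA\nCCCC\n")
        m = read_count_matrix(tmp_path)
        assert list(m.totals_per_barcode()) == [5, 2]
        assert m.matrix[0, 0] == 5 and m.matrix[2, 1] == 2

    def test_empty_matrix_is_valid(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 2 0\n"
        )
        (tmp_path / "features.tsv").write_text("g1\thuman\tFalse\ng2\thuman\tFalse\n")
        (tmp_path / "barcodes.tsv").write_text("AAAA\nCCCC\n")
        m = read_count_matrix(tmp_path)
        assert list(m.totals_per_barcode()) == [0, 0]

    def test_dimension_mismatch_names_sidecar(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n4 1 0\n"
        )
        (tmp_path / "features.tsv").write_text(
            "g1\thuman\tFalse\ng2\thuman\tFalse\ng3\thuman\tFalse\n"
        )
        (tmp_path / "barcodes.tsv").write_text("AAAA\n")
        with pytest.raises(FormatError, match="features.tsv"):
            read_count_matrix(tmp_path)

    def test_negative_entries_rejected(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n1 1 1\n1 1 -3\n"
        )
        (tmp_path / "features.tsv").write_text("g1\thuman\tFalse\n")
        (tmp_path / "barcodes.tsv").write_text("AAAA\n")
        with pytest.raises(FormatError, match="negative"):
            read_count_matrix(tmp_path)

    def test_round_trip_identity(self, tmp_path, two_species_features, make_toy_matrix):
        m = make_toy_matrix(
            [[5, 0], [0, 2], [1, 1], [0, 0], [3, 0], [0, 7]],
            two_species_features,
            ["ACGTNACGTNACGTNA", "TTTTTTTTTTTTTTTT"],  # N preserved verbatim
            raw_reads=[20, 15],
        )
        write_count_matrix(m, tmp_path / "out")
        back = read_count_matrix(tmp_path / "out")
        assert m.equals(back)

    def test_file_size_scales_with_nonzeros(self, tmp_path, two_species_features, make_toy_matrix):
        rng = np.random.default_rng(0)
        barcodes = [f"BC{i:05d}" for i in range(2000)]
        dense = rng.poisson(0.3, size=(6, 2000))
        m = make_toy_matrix(dense, two_species_features, barcodes)
        write_count_matrix(m, tmp_path / "out")
        lines = (tmp_path / "out" / "matrix.mtx").read_text().splitlines()
        data_lines = [l for l in lines if l and not l.startswith("%")]
        assert len(data_lines) == m.matrix.nnz + 1  # shape line + one line/nonzero


class TestTaggedReadTSV:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "barcode": ["A" * 16, "C" * 16],
                "umi": ["G" * 12, "T" * 12],
                "gene": ["g1", UNASSIGNED],
                "species": ["human", UNASSIGNED],
            }
        )
        write_tagged_reads(df, tmp_path / "reads.tsv")
        back = read_tagged_reads(tmp_path / "reads.tsv")
        pd.testing.assert_frame_equal(df, back)


def _fastq(records):
    return io.StringIO("".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(records)))


@pytest.fixture()
def catalog():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    return TranscriptCatalog(
        {f"g{i}": "".join(rng.choice(bases, 100)) for i in range(4)}, k=31
    )


class TestParseFastqPair:
    layout = ReadLayout()

    def test_exact_transcript_prefix_assigns_gene(self, catalog):
        r1 = _fastq(["A" * 16 + "C" * 12 + "GG"])
        r2 = _fastq([catalog.transcripts["g2"][:70]])
        reads, report = parse_fastq_pair(r1, r2, self.layout, catalog, {"g2": "human"})
        assert list(reads["gene"]) == ["g2"]
        assert list(reads["species"]) == ["human"]
        assert report.reconciles()

    def test_unknown_sequence_is_unassigned(self, catalog):
        r1 = _fastq(["A" * 30])
        r2 = _fastq(["AC" * 35])
        reads, _ = parse_fastq_pair(r1, r2, self.layout, catalog)
        assert list(reads["gene"]) == [UNASSIGNED]

    def test_n_in_barcode_or_umi_drops_read(self, catalog):
        r1 = _fastq(["N" + "A" * 29, "A" * 16 + "N" + "C" * 13, "A" * 30])
        seq = catalog.transcripts["g0"][:70]
        r2 = _fastq([seq, seq, seq])
        reads, report = parse_fastq_pair(r1, r2, self.layout, catalog)
        assert report == ParseReport(total_records=3, emitted=1, dropped_n=2)
        assert len(reads) == 1

    def test_unequal_record_counts_raise(self, catalog):
        r1 = _fastq(["A" * 30, "C" * 30])
        r2 = _fastq([catalog.transcripts["g0"][:70]])
        with pytest.raises(SynchronizationError):
            parse_fastq_pair(r1, r2, self.layout, catalog)

    def test_short_r1_raises_layout_error(self, catalog):
        r1 = _fastq(["A" * 20])
        r2 = _fastq([catalog.transcripts["g0"][:70]])
        with pytest.raises(LayoutError):
            parse_fastq_pair(r1, r2, self.layout, catalog)

    def test_zero_error_simulation_recovered_exactly(self, small_experiment, tmp_path):
        """With no sequencing errors the parser must invert the generator."""
        from barnyardqc import write_fastq_pair

        exp = small_experiment
        write_fastq_pair(exp, tmp_path / "R1.fastq", tmp_path / "R2.fastq")
        species_of = dict(zip(exp.features["gene_id"], exp.features["species"]))
        reads, report = parse_fastq_pair(
            tmp_path / "R1.fastq", tmp_path / "R2.fastq",
            ReadLayout(), exp.catalog, species_of,
        )
        assert report.reconciles()
        assert report.total_records == exp.n_raw_reads
        key = ["barcode", "umi", "gene", "species"]
        got = reads.sort_values(key).reset_index(drop=True)
        want = exp.reads.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)


def test_feature_table_rejects_duplicate_genes():
    from barnyardqc import ConsistencyError

    with pytest.raises(ConsistencyError):
        make_feature_table(["g1", "g1"], ["human", "human"], [False, False])


def test_raw_reads_must_cover_transcripts(two_species_features):
    with pytest.raises(Exception, match="raw read count"):
        CountMatrix(
            sp.csr_matrix(np.full((6, 1), 2, dtype=np.int64)),
            two_species_features,
            np.array(["AAAA"], dtype=object),
            raw_reads=np.array([3]),
        )
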