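"""Alignment reading, normalisation, filtering and site summaries."""

import pytest

from baitdesign.alignment import (
    count_variable_sites,
    degap,
    filter_taxa,
    read_fasta_alignment,
    read_keep_list,
    trim_gap_only_columns,
    write_fasta_alignment,
)
from baitdesign.errors import (
    AlignmentShapeError,
    AlphabetError,
    DuplicateIdError,
    EmptyAlignmentError,
    InputError,
    TooFewSequencesError,
)
from conftest import make_alignment


class TestReadFasta:
    def test_parses_gapped_records(self, write_fasta):
        path = write_fasta({"a": "AC-GT", "b": "ACAGT"})
        aln = read_fasta_alignment(path)
        assert aln.n_columns == 5
        assert aln.ids == ["a", "b"]
        assert aln["a"].residues == "AC-GT"

    def test_normalizes_case_and_u(self, write_fasta):
        path = write_fasta({"a": "acugu", "b": "ACGTA"})
        aln = read_fasta_alignment(path)
        assert aln["a"].residues == "ACTGT"

    def test_unequal_lengths_rejected(self, write_fasta):
        path = write_fasta({"a": "ACGTA", "b": "ACGT"})
        with pytest.raises(AlignmentShapeError):
            read_fasta_alignment(path)

    def test_illegal_symbol_rejected(self, write_fasta):
        path = write_fasta({"a": "AC!GT", "b": "ACGTT"})
        with pytest.raises(AlphabetError):
            read_fasta_alignment(path)

    def test_single_record_rejected(self, write_fasta):
        path = write_fasta({"a": "ACGT"})
        with pytest.raises(TooFewSequencesError):
            read_fasta_alignment(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACGT\n>a\nACGA\n")
        with pytest.raises(DuplicateIdError):
            read_fasta_alignment(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            read_fasta_alignment(tmp_path / "nope.fasta")

    def test_round_trip_preserves_ids_and_residues(self, tmp_path, write_fasta):
        rows = {"x 1": "ACGT-N", "y": "RYGTAC"}
        path = write_fasta(rows)
        aln = read_fasta_alignment(path)
        assert aln.ids == ["x", "y"]  # id is the first header token
        out = tmp_path / "out.fasta"
        write_fasta_alignment(aln, out)
        aln2 = read_fasta_alignment(out)
        assert aln2.ids == aln.ids
        assert [r.residues for r in aln2.records] == [r.residues for r in aln.records]


class TestFilterTaxa:
    def test_keeps_subset_in_order(self):
        aln = make_alignment({f"s{i}": "ACGT" for i in range(5)})
        out = filter_taxa(aln, {"s3", "s0", "s4"})
        assert out.ids == ["s0", "s3", "s4"]

    def test_keep_all_is_identity(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA"})
        out = filter_taxa(aln, {"a", "b"})
        assert out.ids == aln.ids

    def test_too_few_left_raises(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA", "c": "ACGC"})
        with pytest.raises(TooFewSequencesError):
            filter_taxa(aln, {"a"})

    def test_keep_list_file(self, tmp_path):
        path = tmp_path / "keep.txt"
        path.write_text("# comment\ns1\ns2  # inline\n\n")
        assert read_keep_list(path) == {"s1", "s2"}


class TestTrim:
    def test_removes_all_gap_columns(self):
        aln = make_alignment({"a": "A-C", "b": "A-G"})
        out = trim_gap_only_columns(aln)
        assert out.n_columns == 2
        assert [r.residues for r in out.records] == ["AC", "AG"]

    def test_identity_when_no_gap_only_columns(self):
        aln = make_alignment({"a": "A-C", "b": "AGG"})
        assert trim_gap_only_columns(aln) is aln

    def test_all_gap_alignment_raises(self):
        aln = make_alignment({"a": "---", "b": "---"})
        with pytest.raises(EmptyAlignmentError):
            trim_gap_only_columns(aln)

    def test_idempotent(self):
        aln = make_alignment({"a": "A--C-", "b": "AC-G-", "c": "AA-T-"})
        once = trim_gap_only_columns(aln)
        twice = trim_gap_only_columns(once)
        assert [r.residues for r in twice.records] == [
            r.residues for r in once.records
        ]

    def test_preserves_ambiguity_codes(self):
        aln = make_alignment({"a": "R-Y", "b": "N-W"})
        out = trim_gap_only_columns(aln)
        assert [r.residues for r in out.records] == ["RY", "NW"]


class TestDegap:
    @pytest.mark.parametrize(
        "residues,expected",
        [("AC-GT", "ACGT"), ("-----", ""), ("ACGT", "ACGT"), ("-A-C-", "AC")],
    )
    def test_examples(self, residues, expected):
        assert degap(residues) == expected

    def test_length_identity(self):
        aln = make_alignment({"a": "A-C-GT--N", "b": "ACGTACGTA"})
        for rec in aln.records:
            assert len(degap(rec)) == len(rec) - rec.residues.count("-")


class TestVariableSites:
    def test_identical_records_zero(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        assert count_variable_sites(aln) == (4, 0)

    def test_single_variable_column(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA"})
        assert count_variable_sites(aln) == (4, 1)

    def test_gaps_and_ambiguity_do_not_create_variability(self):
        aln = make_alignment({"a": "AC-T", "b": "ACGT", "c": "ACGT"})
        assert count_variable_sites(aln) == (4, 0)
        aln = make_alignment({"a": "RCNT", "b": "ACGT"})
        assert count_variable_sites(aln) == (4, 0)

    def test_bounded_by_n_columns(self):
        aln = make_alignment({"a": "ACGTAC", "b": "TGCAGT"})
        total, var = count_variable_sites(aln)
        assert total == 6 and var <= total
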