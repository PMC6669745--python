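import math

import pytest
from hypothesis import given, settings, strategies as st

from actinovar.sequences import (Alphabet, FastaParseError, OverlapConflictError,
                                 SequenceRecord, WATER_MASS, average_mass,
                                 pairwise_compare, read_fasta, region_differences,
                                 splice_mature, translate_cds, write_fasta)

AA = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid, for translation round trips
CODON = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
         "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
         "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
         "W": "TGG", "Y": "TAT"}


class TestFasta:
    def test_roundtrip_preserves_order_and_content(self, tmp_path):
        recs = [SequenceRecord("x", "ACDE"), SequenceRecord("y", "GGWW")]
        path = tmp_path / "t.fasta"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.seq) for r in back] == [("x", "ACDE"), ("y", "GGWW")]

    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">x\nACDE\n")
        (rec,) = read_fasta(path)
        assert rec.id == "x" and rec.seq == "ACDE"

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(FastaParseError):
            read_fasta(path)

    def test_missing_header_raises_with_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACDE\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(path)


class TestTranslate:
    @pytest.mark.parametrize("cds,frame,expected", [
        ("ATGGCT", 0, "MA"),
        ("ATGTAAGCT", 0, "M"),          # stop truncates
        ("GATGGCT", 1, "MA"),           # frame offset
        ("ATGNNNGCT", 0, "MXA"),        # N codon -> X
    ])
    def test_standard_code(self, cds, frame, expected):
        rec = SequenceRecord("c", cds, Alphabet.DNA)
        assert translate_cds(rec, frame=frame).seq == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            translate_cds(SequenceRecord("c", "AT", Alphabet.DNA))

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("c", "ATR", Alphabet.DNA)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.text(alphabet=AA, min_size=1, max_size=40))
    def test_roundtrip_through_codons(self, protein):
        cds = "".join(CODON[aa] for aa in protein)
        rec = SequenceRecord("p", cds, Alphabet.DNA)
        assert translate_cds(rec).seq == protein


class TestSplice:
    def test_declared_overlap_joins(self):
        assert splice_mature("AB", "BC", overlap=1).full == "ABC"

    def test_overlap_conflict_reports_position(self):
        with pytest.raises(OverlapConflictError, match="position 2"):
            splice_mature("AB", "XC", overlap=1)

    def test_no_overlap_concatenates(self):
        m = splice_mature("SAEVAGAIIDGA", "SLTFDVLQ")
        assert m.full == "SAEVAGAIIDGASLTFDVLQ"
        assert m.full.startswith(m.edman_prefix)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            splice_mature("", "AC")


class TestMass:
    def test_water_only_for_empty(self):
        assert average_mass("") == pytest.approx(WATER_MASS)

    def test_diglycine(self):
        # independent hand sum: 2 x 57.05 + 18.0153
        assert average_mass("GG") == pytest.approx(132.12, abs=0.01)

    def test_unknown_symbol(self):
        with pytest.raises(ValueError):
            average_mass("GZ")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.text(alphabet=AA, max_size=30), st.text(alphabet=AA, max_size=30))
    def test_additive_up_to_water(self, a, b):
        assert average_mass(a + b) == pytest.approx(
            average_mass(a) + average_mass(b) - WATER_MASS, abs=1e-6)


class TestPairwise:
    def test_self_comparison(self):
        a = SequenceRecord("a", "ACDEFG")
        cmp = pairwise_compare(a, a)
        assert cmp.n_different == 0 and cmp.pct_identity == 100.0

    def test_counts_partition(self):
        a = SequenceRecord("a", "ACDE")
        b = SequenceRecord("b", "ACDW")
        cmp = pairwise_compare(a, b)
        assert (cmp.n_identical, cmp.n_different, cmp.n_aligned) == (3, 1, 4)
        assert cmp.pct_identity == pytest.approx(75.0)

    def test_gapped_columns_excluded_from_denominator(self):
        a = SequenceRecord("a", "AC-E")
        b = SequenceRecord("b", "ACDE")
        cmp = pairwise_compare(a, b)
        assert cmp.n_aligned == 3 and cmp.n_identical == 3

    def test_global_mode_aligns_first(self):
        a = SequenceRecord("a", "ACDEFGHIKL")
        b = SequenceRecord("b", "ACDEGHIKL")  # F deleted
        cmp = pairwise_compare(a, b, mode="global")
        assert cmp.n_identical == 9 and cmp.n_different == 0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.text(alphabet=AA, min_size=5, max_size=25),
           st.text(alphabet=AA, min_size=5, max_size=25))
    def test_symmetric(self, sa, sb):
        a, b = SequenceRecord("a", sa), SequenceRecord("b", sb)
        x = pairwise_compare(a, b, mode="global")
        y = pairwise_compare(b, a, mode="global")
        assert (x.n_identical, x.n_different) == (y.n_identical, y.n_different)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_compare(SequenceRecord("a", "A"), SequenceRecord("b", ""))


class TestRegionDifferences:
    def test_identical_sequences_zero(self):
        a = SequenceRecord("a", "ACDEFGHIKL")
        assert region_differences(a, a, 1, 10) == 0

    def test_counts_only_inside_region(self):
        a = SequenceRecord("a", "ACDEFGHIKL")
        b = SequenceRecord("b", "WCDEFGHIKW")
        assert region_differences(a, b, 1, 5) == 1
        assert region_differences(a, b, 2, 9) == 0
        assert region_differences(a, b, 1, 10) == 2

    def test_reference_numbering_skips_reference_gaps(self):
        a = SequenceRecord("a", "A-CDE")
        b = SequenceRecord("b", "AWCDX")
        # reference positions: A=1 C=2 D=3 E=4; only E(4) differs
        assert region_differences(a, b, 1, 3) == 0
        assert region_differences(a, b, 4, 4) == 1

    def test_out_of_range(self):
        a = SequenceRecord("a", "ACDE")
        with pytest.raises(ValueError):
            region_differences(a, a, 3, 2)
        with pytest.raises(ValueError):
            region_differences(a, a, 1, 9)
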