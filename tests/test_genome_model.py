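"""Core data types, FASTA/catalogue IO and the MAF computation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paralogtrap as pt
from paralogtrap.errors import (
    CatalogueError,
    CoordinateError,
    FastaFormatError,
)
from paralogtrap.genome_model import (
    load_variant_calls,
    write_snp_catalogue,
    write_variant_calls,
)


class TestFasta:
    def test_single_record_is_uppercased(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">x\nacgt\n")
        assert pt.read_fasta(f) == [("x", "ACGT")]

    def test_two_records_keep_file_order(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">b\nAAA\n>a\nCCC\n")
        assert [name for name, _ in pt.read_fasta(f)] == ["b", "a"]

    def test_disallowed_character_rejected(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">x\nACGZ\n")
        with pytest.raises(FastaFormatError):
            pt.read_fasta(f)

    def test_missing_header_rejected(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text("ACGT\n")
        with pytest.raises(FastaFormatError):
            pt.read_fasta(f)

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text("")
        assert pt.read_fasta(f) == []

    def test_write_read_round_trip(self, tmp_path):
        records = [("one", "ACGTN"), ("two", "TTTTACGT")]
        f = tmp_path / "rt.fasta"
        pt.write_fasta(records, f)
        assert pt.read_fasta(f) == records


class TestExtractLocus:
    GENOME = ("chrT", "AACGTT")

    def test_whole_sequence_identity(self):
        locus = pt.extract_locus(
            self.GENOME, pt.GenomicInterval("chrT", 1, 6), "+"
        )
        assert locus.sequence == "AACGTT"
        assert locus.strand == "+"

    def test_one_based_inclusive_subsequence(self):
        locus = pt.extract_locus(
            self.GENOME, pt.GenomicInterval("chrT", 2, 4), "+"
        )
        assert locus.sequence == "ACG"

    def test_minus_strand_is_reverse_complement(self):
        locus = pt.extract_locus(
            self.GENOME, pt.GenomicInterval("chrT", 2, 4), "-"
        )
        assert locus.sequence == "CGT"
        assert locus.strand == "-"

    def test_double_reverse_complement_restores_plus_strand(self):
        interval = pt.GenomicInterval("chrT", 2, 5)
        minus = pt.extract_locus(self.GENOME, interval, "-")
        plus = pt.extract_locus(self.GENOME, interval, "+")
        assert pt.reverse_complement(minus.sequence) == plus.sequence

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(CoordinateError):
            pt.extract_locus(self.GENOME, pt.GenomicInterval("chrT", 3, 9), "+")

    def test_minus_strand_coordinate_mapping(self):
        locus = pt.extract_locus(self.GENOME, pt.GenomicInterval("chrT", 2, 4), "-")
        # stored offset 0 is the highest genomic position
        assert locus.genomic_position(0) == 4
        assert locus.offset_of(4) == 0
        assert locus.base_at(2) == "A"  # forward-strand base


class TestIntervalInvariants:
    def test_length_is_inclusive(self):
        assert pt.GenomicInterval("chr9", 80537082, 80537222).length == 141

    @pytest.mark.parametrize("start,end", [(0, 5), (5, 4)])
    def test_bad_intervals_rejected(self, start, end):
        with pytest.raises(CoordinateError):
            pt.GenomicInterval("chr1", start, end)


class TestSnpCatalogue:
    ROW = "rs753716491\tchr9\t80537112\tT\tA\t1386\t117782\n"
    HEADER = "rsid\tcontig\tposition\tref\talt\tallele_count\ttotal_alleles\n"

    def test_single_row_loads(self, tmp_path):
        f = tmp_path / "cat.tsv"
        f.write_text(self.HEADER + self.ROW)
        (rec,) = pt.load_snp_catalogue(f)
        assert rec.rsid == "rs753716491"
        assert (rec.contig, rec.position) == ("chr9", 80537112)
        assert (rec.ref_allele, rec.alt_allele) == ("T", "A")
        assert rec.maf == 1.18

    def test_empty_file_gives_empty_catalogue(self, tmp_path):
        f = tmp_path / "cat.tsv"
        f.write_text("")
        assert pt.load_snp_catalogue(f) == []

    def test_duplicate_site_rejected(self, tmp_path):
        f = tmp_path / "cat.tsv"
        f.write_text(self.HEADER + self.ROW + self.ROW)
        with pytest.raises(CatalogueError):
            pt.load_snp_catalogue(f)

    def test_count_exceeding_total_rejected(self, tmp_path):
        f = tmp_path / "cat.tsv"
        f.write_text(self.HEADER + "rs1\tchr1\t10\tA\tC\t20\t10\n")
        with pytest.raises(CatalogueError):
            pt.load_snp_catalogue(f)

    def test_catalogue_round_trip(self, tmp_path, pair):
        f = tmp_path / "cat.tsv"
        write_snp_catalogue(pair.catalogue, f)
        assert tuple(pt.load_snp_catalogue(f)) == pair.catalogue

    def test_vcf_catalogue(self, tmp_path):
        vcf = tmp_path / "cat.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AC,Number=A,Type=Integer,Description="ac">\n'
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="an">\n'
            "##contig=<ID=chr9>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr9\t80537112\trs753716491\tT\tA\t.\t.\tAC=1386;AN=117782\n"
        )
        (rec,) = pt.load_snp_catalogue(vcf)
        assert rec.rsid == "rs753716491" and rec.maf == 1.18


class TestComputeMaf:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(1386, 117782, 1.18), (0, 100, 0.0), (50, 100, 50.0), (1, 800, 0.13)],
    )
    def test_worked_examples(self, count, total, expected):
        assert pt.compute_maf(count, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(CatalogueError):
            pt.compute_maf(1, 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        total=st.integers(min_value=1, max_value=10**6),
        data=st.data(),
    )
    def test_monotone_in_allele_count(self, total, data):
        lo = data.draw(st.integers(min_value=0, max_value=total))
        hi = data.draw(st.integers(min_value=lo, max_value=total))
        assert pt.compute_maf(lo, total) <= pt.compute_maf(hi, total)


class TestVariantCalls:
    def test_depth_invariant(self):
        with pytest.raises(CoordinateError):
            pt.VariantCall("chr1", 5, "A", "C", alt_depth=4, total_depth=3)

    def test_tsv_round_trip(self, tmp_path):
        calls = [
            pt.VariantCall("chr9", 80537095, "G", "T", 3, 37),
            pt.VariantCall("chr9", 80537112, "T", "A", 9, 71),
        ]
        f = tmp_path / "calls.tsv"
        write_variant_calls(calls, f)
        loaded = load_variant_calls(f)
        assert [(c.position, c.ref, c.alt, c.alt_depth, c.total_depth)
                for c in loaded] == [
            (80537095, "G", "T", 3, 37), (80537112, "T", "A", 9, 71)]

    def test_contig_normalization_in_matching(self):
        a = pt.VariantCall("chr9", 10, "A", "C")
        b = pt.VariantCall("9", 10, "A", "C")
        assert a.key == b.key
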