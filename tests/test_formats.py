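import pytest

from varbench.errors import ParseError, UnsupportedVariantError
from varbench.formats import (DepthTrack, RegionSet, depth_from_alignments,
                              read_bed, read_depth_bedgraph, read_fasta,
                              read_vcf, write_bed, write_vcf)

VCF_HEADER = ("##fileformat=VCFv4.2\n"
              "##contig=<ID=chr1,length=1000>\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n")


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadVcf:
    def test_basic_fields(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        (rec,) = read_vcf(p)
        assert (rec.contig, rec.pos, rec.ref, rec.alts) == ("chr1", 5, "A", ("G",))
        assert sorted(rec.genotype) == [0, 1]
        assert rec.passing

    def test_multiallelic_preserved(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t5\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n")
        (rec,) = read_vcf(p)
        assert rec.alts == ("G", "T")
        assert sorted(rec.genotype) == [1, 2]

    def test_empty_body(self, tmp_path):
        assert read_vcf(write(tmp_path, "a.vcf", VCF_HEADER)) == []

    def test_missing_gt_flags_genotype_missing(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t./.\n")
        (rec,) = read_vcf(p)
        assert rec.genotype is None

    def test_filter_status(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
                  '##FILTER=<ID=q10,Description="x">\n'
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
                  "chr1\t5\t.\tA\tG\t.\tq10\t.\tGT\t0/1\n"
                  "chr1\t9\t.\tC\tT\t.\t.\t.\tGT\t0/1\n")
        recs = read_vcf(p)
        assert [r.passing for r in recs] == [False, True]
        assert read_vcf(p, passing_only=True)[0].pos == 9

    def test_symbolic_allele_rejected(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t5\t.\tA\t<DEL>\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(UnsupportedVariantError):
            read_vcf(p)

    def test_malformed_record_errors(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\tnotanumber\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ParseError):
            read_vcf(p)

    def test_roundtrip(self, tmp_path):
        p = write(tmp_path, "a.vcf",
                  VCF_HEADER + "chr1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
                               "chr1\t9\t.\tCT\tC\t.\tPASS\t.\tGT\t1/1\n")
        recs = read_vcf(p)
        out = tmp_path / "b.vcf"
        write_vcf(recs, out, {"chr1": 1000})
        again = read_vcf(out)
        assert [(r.contig, r.pos, r.ref, r.alts, r.zygosity) for r in recs] == \
               [(r.contig, r.pos, r.ref, r.alts, r.zygosity) for r in again]


class TestReadBed:
    def test_overlap_merged(self, tmp_path):
        rs = read_bed(write(tmp_path, "a.bed", "chr1\t0\t10\nchr1\t5\t15\n"))
        assert rs.regions("chr1") == [(0, 15)]

    def test_adjacency_merged(self, tmp_path):
        rs = read_bed(write(tmp_path, "a.bed", "chr1\t0\t5\nchr1\t5\t10\n"))
        assert rs.regions("chr1") == [(0, 10)]

    def test_empty_file(self, tmp_path):
        assert not read_bed(write(tmp_path, "a.bed", ""))

    def test_invalid_interval_names_line(self, tmp_path):
        with pytest.raises(ParseError, match="2"):
            read_bed(write(tmp_path, "a.bed", "chr1\t0\t5\nchr1\t9\t9\n"))

    def test_roundtrip_identity(self, tmp_path):
        rs = RegionSet([("chr1", 3, 9), ("chr2", 0, 4), ("chr1", 20, 30)])
        write_bed(rs, tmp_path / "out.bed")
        assert read_bed(tmp_path / "out.bed") == rs


class TestReadFasta:
    def test_uppercase(self, tmp_path):
        seqs = read_fasta(write(tmp_path, "a.fa", ">c1\nacgt\n"))
        assert seqs == {"c1": "ACGT"}

    def test_two_contigs(self, tmp_path):
        seqs = read_fasta(write(tmp_path, "a.fa", ">c1\nAC\n>c2\nGT\n"))
        assert len(seqs) == 2

    def test_name_tokenization(self, tmp_path):
        seqs = read_fasta(write(tmp_path, "a.fa", ">c1 some description\nAC\n"))
        assert list(seqs) == ["c1"]

    def test_duplicate_contig(self, tmp_path):
        with pytest.raises(ParseError, match="duplicate"):
            read_fasta(write(tmp_path, "a.fa", ">c1\nAC\n>c1\nGT\n"))


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"


def sam_line(name, pos, mapq, cigar, flag=0):
    seq_len = sum(int(n) for n, op in
                  __import__("re").findall(r"(\d+)([MIDNSHP=X])", cigar)
                  if op in "MIS=X")
    return (f"{name}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
            f"{'A' * seq_len}\t*\n")


class TestDepthFromAlignments:
    def test_single_read(self, tmp_path):
        p = write(tmp_path, "a.sam", SAM_HEADER + sam_line("r1", 1, 60, "10M"))
        assert depth_from_alignments(p).runs("chr1") == [(0, 10, 1)]

    def test_mapq_filter(self, tmp_path):
        p = write(tmp_path, "a.sam", SAM_HEADER + sam_line("r1", 1, 59, "10M"))
        assert depth_from_alignments(p, mapq_min=60).runs("chr1") == []

    def test_deletion_consumes_reference(self, tmp_path):
        p = write(tmp_path, "a.sam", SAM_HEADER + sam_line("r1", 1, 60, "5M2D5M"))
        assert depth_from_alignments(p).runs("chr1") == [(0, 12, 1)]

    def test_intron_skip_not_counted(self, tmp_path):
        p = write(tmp_path, "a.sam", SAM_HEADER + sam_line("r1", 1, 60, "5M3N5M"))
        assert depth_from_alignments(p).runs("chr1") == [(0, 5, 1), (8, 13, 1)]

    def test_secondary_excluded(self, tmp_path):
        p = write(tmp_path, "a.sam",
                  SAM_HEADER + sam_line("r1", 1, 60, "10M", flag=256))
        assert depth_from_alignments(p).runs("chr1") == []

    def test_additivity(self, tmp_path):
        lines = "".join(sam_line(f"r{i}", 3, 60, "4M2D3M") for i in range(4))
        p = write(tmp_path, "a.sam", SAM_HEADER + lines)
        single = write(tmp_path, "b.sam", SAM_HEADER + sam_line("r0", 3, 60, "4M2D3M"))
        four = depth_from_alignments(p)
        one = depth_from_alignments(single)
        assert [(s, e, 4 * d) for s, e, d in one.runs("chr1")] == four.runs("chr1")

    def test_unsorted_errors(self, tmp_path):
        p = write(tmp_path, "a.sam",
                  SAM_HEADER + sam_line("r1", 50, 60, "10M") + sam_line("r2", 1, 60, "10M"))
        with pytest.raises(ParseError, match="sorted"):
            depth_from_alignments(p)


class TestReadDepthBedgraph:
    def test_equal_depth_merge(self, tmp_path):
        t = read_depth_bedgraph(
            write(tmp_path, "a.bg", "chr1\t0\t10\t5\nchr1\t10\t20\t5\n"))
        assert t.runs("chr1") == [(0, 20, 5)]

    def test_distinct_depths(self, tmp_path):
        t = read_depth_bedgraph(
            write(tmp_path, "a.bg", "chr1\t0\t10\t5\nchr1\t10\t20\t7\n"))
        assert t.runs("chr1") == [(0, 10, 5), (10, 20, 7)]

    def test_negative_depth(self, tmp_path):
        with pytest.raises(ParseError, match="negative"):
            read_depth_bedgraph(write(tmp_path, "a.bg", "chr1\t0\t10\t-1\n"))

    def test_overlapping_runs(self, tmp_path):
        with pytest.raises(ParseError, match="overlap"):
            read_depth_bedgraph(
                write(tmp_path, "a.bg", "chr1\t0\t10\t5\nchr1\t5\t20\t7\n"))


class TestRegionSet:
    def test_intersection(self):
        a = RegionSet([("c", 0, 10)])
        b = RegionSet([("c", 5, 15)])
        assert a.intersect(b).regions("c") == [(5, 10)]
        assert a.intersect(b) == b.intersect(a)

    def test_disjoint_intersection_empty(self):
        assert not RegionSet([("c", 0, 5)]).intersect(RegionSet([("c", 7, 9)]))

    def test_self_intersection_identity(self):
        a = RegionSet([("c", 0, 5), ("c", 8, 12), ("d", 1, 4)])
        assert a.intersect(a) == a

    def test_contains(self):
        a = RegionSet([("c", 3, 7)])
        assert not a.contains("c", 2)
        assert a.contains("c", 3)
        assert a.contains("c", 6)
        assert not a.contains("c", 7)
        assert not a.contains("x", 3)


class TestDepthTrack:
    def test_equal_adjacent_merge(self):
        t = DepthTrack([("c", 0, 5, 3), ("c", 5, 9, 3)])
        assert t.runs("c") == [(0, 9, 3)]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DepthTrack([("c", 0, 5, 3), ("c", 4, 9, 3)])
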