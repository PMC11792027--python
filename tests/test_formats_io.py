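"""Coordinate conventions, parsers, and round-trip losslessness."""

import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoformatlas.formats_io import (
    Annotation,
    GenomicInterval,
    JunctionTable,
    ParseError,
    SplicedRead,
    read_fasta,
    read_gtf,
    read_junctions,
    read_peaks,
    read_reads,
    write_gtf,
    write_reads,
)
from conftest import make_transcript


class TestGenomicInterval:
    def test_rejects_inverted_and_bad_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100, "+")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100, "+")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, "?")

    def test_half_open_membership(self):
        iv = GenomicInterval("chr1", 500, 700, "+")
        assert iv.contains(500) and iv.contains(699)
        assert not iv.contains(700)


class TestGtf:
    GTF = (
        "##comment\n"
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    )

    def test_coordinates_converted_to_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(self.GTF)
        ann = read_gtf(p)
        t = ann.transcripts["t1"]
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]
        assert t.gene_id == "g1"

    def test_out_of_order_exons_are_sorted(self, tmp_path):
        lines = self.GTF.splitlines()
        p = tmp_path / "a.gtf"
        p.write_text("\n".join([lines[0], lines[2], lines[1]]) + "\n")
        t = read_gtf(p).transcripts["t1"]
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]

    @pytest.mark.parametrize(
        "bad_line,msg",
        [
            ('chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g1";', "missing"),
            ('chr1\ts\texon\t300\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";', "end < start"),
            ('chr1\ts\texon\t101\t200\t.\t?\t.\tgene_id "g"; transcript_id "t";', "strand"),
        ],
    )
    def test_parse_errors_name_the_line(self, tmp_path, bad_line, msg):
        p = tmp_path / "bad.gtf"
        p.write_text("# header\n" + bad_line + "\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gtf(p)

    def test_round_trip_identity(self, tmp_path, two_gene_annotation):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(two_gene_annotation, p1)
        ann1 = read_gtf(p1)
        write_gtf(ann1, p2)
        ann2 = read_gtf(p2)
        assert p1.read_text() == p2.read_text()
        assert set(ann1.transcripts) == set(two_gene_annotation.transcripts)
        for tid, t in ann2.transcripts.items():
            orig = two_gene_annotation.transcripts[tid]
            assert [(e.start, e.end) for e in t.exons] == [
                (e.start, e.end) for e in orig.exons
            ]
            assert t.gene_id == orig.gene_id

    def test_cds_round_trip(self, tmp_path):
        t = make_transcript(
            "t1", "g1", [(100, 200), (300, 400)], cds=[(150, 200), (300, 350)]
        )
        p = tmp_path / "c.gtf"
        write_gtf(Annotation.from_transcripts([t]), p)
        back = read_gtf(p).transcripts["t1"]
        assert [(c.start, c.end) for c in back.cds] == [(150, 200), (300, 350)]

    def test_empty_annotation_writes_header_only(self, tmp_path):
        p = tmp_path / "e.gtf"
        write_gtf(Annotation(), p)
        assert p.read_text().startswith("#")
        assert len(read_gtf(p)) == 0

    @settings(max_examples=50, deadline=None)
    @given(
        start=st.integers(min_value=0, max_value=10_000),
        length=st.integers(min_value=1, max_value=5_000),
    )
    def test_gtf_one_based_closed_conversion_roundtrip(self, tmp_path_factory, start, length):
        """Internal [start, end) maps to GTF (start+1, end) and back."""
        t = make_transcript("t", "g", [(start, start + length)])
        p = tmp_path_factory.mktemp("rt") / "x.gtf"
        write_gtf(Annotation.from_transcripts([t]), p)
        line = [l for l in p.read_text().splitlines() if "\texon\t" in l][0]
        f = line.split("\t")
        assert (int(f[3]), int(f[4])) == (start + 1, start + length)
        back = read_gtf(p).transcripts["t"].exons[0]
        assert (back.start, back.end) == (start, start + length)


class TestReads:
    def test_five_prime_pos_strand_rule(self):
        r = SplicedRead("r1", "chr1", "-", ((100, 200), (300, 400)))
        assert r.five_prime_pos == 400
        assert SplicedRead("r2", "chr1", "+", ((100, 200),)).five_prime_pos == 100

    def test_junctions_from_blocks(self):
        r = SplicedRead("r1", "chr1", "+", ((100, 200), (300, 400), (500, 600)))
        assert r.junctions == ((200, 300), (400, 500))

    def test_round_trip_preserves_all_fields(self, tmp_path):
        reads = [
            SplicedRead("r1", "chr1", "+", ((100, 200), (300, 400)), 12, 60, 85.5),
            SplicedRead("r2", "chr2", "-", ((5, 50),), 0, 0, None),
        ]
        p = tmp_path / "reads.tsv"
        write_reads(reads, p)
        back = read_reads(p)
        assert len(back) == 2
        assert back[0].blocks == reads[0].blocks
        assert back[0].polya_length == pytest.approx(85.5)
        assert back[1].polya_length is None
        assert back[1].mapq == 0

    def test_ragged_blocks_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("r1\tchr1\t+\t100,300\t200\t0\t60\t\n")
        with pytest.raises(ParseError, match="line 1"):
            read_reads(p)

    def test_negative_fields_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("r1\tchr1\t+\t100\t200\t-5\t60\t\n")
        with pytest.raises(ParseError):
            read_reads(p)


class TestOtherFormats:
    def test_bed_native_zero_based(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t500\t700\tpeak1\t100\t+\n")
        peaks = read_peaks(p)
        assert peaks.contains_point("chr1", 500)
        assert peaks.contains_point("chr1", 699)
        assert not peaks.contains_point("chr1", 700)

    def test_junction_support_parsed_as_int(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("chr1\t200\t300\t+\t3\n")
        table = read_junctions(p)
        assert table.support[("chr1", 200, 300, "+")] == 3

    def test_junction_donor_after_acceptor_rejected(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("chr1\t300\t200\t+\t3\n")
        with pytest.raises(ParseError):
            read_junctions(p)

    def test_fasta_uppercased_and_gzip_transparent(self, tmp_path):
        p = tmp_path / "g.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">chr1\nacGTn\nAAAA\n")
        genome = read_fasta(p)
        assert genome["chr1"] == "ACGTNAAAA"

    def test_junction_window_candidates(self):
        table = JunctionTable()
        table.add("chr1", 1000, 2000, "+", 5)
        table.add("chr1", 1010, 2014, "+", 7)
        table.add("chr1", 5000, 6000, "+", 9)
        hits = table.candidates("chr1", "+", 1002, 2004, window=15)
        assert {(d, a) for d, a, _ in hits} == {(1000, 2000), (1010, 2014)}
        assert table.candidates("chr1", "-", 1002, 2004, 15) == []


class TestTranscriptModel:
    def test_strand_dot_rejected_for_transcripts(self):
        with pytest.raises(ValueError):
            make_transcript("t", "g", [(0, 10)], strand=".")

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            make_transcript("t", "g", [(0, 100), (50, 150)])

    def test_intron_chain(self, two_gene_annotation):
        t = two_gene_annotation.transcripts["tA0"]
        assert t.intron_chain == ((200, 300), (400, 500), (600, 700))

    def test_genomic_to_transcript_minus_strand(self):
        t = make_transcript("t", "g", [(0, 10), (20, 30)], strand="-")
        # position 0 is the transcript's last base on the minus strand
        assert t.genomic_to_transcript(0) == 19
        assert t.genomic_to_transcript(29) == 0
        assert t.genomic_to_transcript(15) is None

    def test_utr_cds_partition(self):
        t = make_transcript(
            "t", "g", [(0, 100), (200, 300)], cds=[(40, 100), (200, 240)]
        )
        assert t.utr_cds_lengths() == (40, 100, 60)
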