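"""Deletion/TSS filters, junction correction, and collapsing."""

import pytest

from isoformatlas.formats_io import (
    GenomicInterval,
    JunctionTable,
    PeakSet,
    SplicedRead,
    read_junctions,
    read_peaks,
    read_reads,
)
from isoformatlas.isoform_refine import (
    CorrectionParams,
    collapse_reads,
    correct_read,
    correct_reads,
    filter_by_deletion,
    filter_by_tss,
    refine,
)
PARAMS = CorrectionParams()


def read_with(deletion=0, blocks=((100, 200), (300, 400)), strand="+", rid="r"):
    return SplicedRead(rid, "chr1", strand, blocks, total_deletion=deletion)


class TestDeletionFilter:
    @pytest.mark.parametrize(
        "deletion,kept", [(0, True), (100, True), (101, False), (500, False)]
    )
    def test_strict_threshold(self, deletion, kept):
        out = filter_by_deletion([read_with(deletion)], PARAMS)
        assert (len(out) == 1) is kept

    def test_order_preserved(self):
        reads = [read_with(5, rid="a"), read_with(200, rid="b"), read_with(0, rid="c")]
        assert [r.read_id for r in filter_by_deletion(reads, PARAMS)] == ["a", "c"]


class TestTssFilter:
    def test_point_in_half_open_peak(self):
        peaks = PeakSet([GenomicInterval("chr1", 500, 700, ".")])
        inside = SplicedRead("r1", "chr1", "+", ((600, 900),))
        boundary = SplicedRead("r2", "chr1", "+", ((700, 900),))
        assert filter_by_tss([inside], peaks) == [inside]
        assert filter_by_tss([boundary], peaks) == []

    def test_minus_strand_uses_rightmost_end(self):
        peaks = PeakSet([GenomicInterval("chr1", 850, 950, ".")])
        r = SplicedRead("r1", "chr1", "-", ((600, 900),))
        assert filter_by_tss([r], peaks) == [r]

    def test_empty_peakset_removes_everything(self):
        assert filter_by_tss([read_with()], PeakSet()) == []


class TestCorrection:
    def table(self, *rows):
        t = JunctionTable()
        for chrom, d, a, strand, n in rows:
            t.add(chrom, d, a, strand, n)
        return t

    def test_snap_within_window(self):
        t = self.table(("chr1", 1000, 2014, "+", 5))
        read = SplicedRead("r", "chr1", "+", ((900, 1000), (2000, 2100)))
        c = correct_read(read, t, PARAMS)
        assert c.status == "corrected"
        assert c.corrected_junctions == ((1000, 2014),)
        assert c.blocks == ((900, 1000), (2014, 2100))

    def test_offset_sixteen_rejected(self):
        t = self.table(("chr1", 1000, 2016, "+", 5))
        read = SplicedRead("r", "chr1", "+", ((900, 1000), (2000, 2100)))
        c = correct_read(read, t, PARAMS)
        assert c.status == "rejected"
        assert c.failing_junction == (1000, 2000)

    @pytest.mark.parametrize("support,status", [(2, "rejected"), (3, "unchanged")])
    def test_min_support_boundary(self, support, status):
        t = self.table(("chr1", 1000, 2000, "+", support))
        read = SplicedRead("r", "chr1", "+", ((900, 1000), (2000, 2100)))
        assert correct_read(read, t, PARAMS).status == status

    def test_tie_broken_by_support_then_donor(self):
        # two candidates at the same max-offset distance
        t = self.table(
            ("chr1", 995, 2000, "+", 3), ("chr1", 1005, 2000, "+", 9)
        )
        read = SplicedRead("r", "chr1", "+", ((900, 1000), (2000, 2100)))
        assert correct_read(read, t, PARAMS).corrected_junctions == ((1005, 2000),)
        t2 = self.table(
            ("chr1", 995, 2000, "+", 5), ("chr1", 1005, 2000, "+", 5)
        )
        assert correct_read(read, t2, PARAMS).corrected_junctions == ((995, 2000),)

    def test_degenerate_exon_rejected(self):
        # snapping would invert the middle exon
        t = self.table(
            ("chr1", 1000, 2010, "+", 5), ("chr1", 2005, 3000, "+", 5)
        )
        read = SplicedRead(
            "r", "chr1", "+", ((900, 1000), (2000, 2007), (2995, 3100))
        )
        c = correct_read(read, t, PARAMS)
        assert c.status == "rejected"
        assert c.reason == "degenerate_exon"

    def test_single_exon_read_unchanged(self):
        c = correct_read(SplicedRead("r", "chr1", "+", ((5, 50),)), JunctionTable(), PARAMS)
        assert c.status == "unchanged"

    def test_filters_idempotent_and_commute(self):
        peaks = PeakSet([GenomicInterval("chr1", 50, 150, ".")])
        reads = [
            read_with(0, ((100, 200), (300, 400)), rid="a"),
            read_with(150, ((100, 200), (300, 400)), rid="b"),
            read_with(0, ((500, 600),), rid="c"),
        ]
        d_then_t = filter_by_tss(filter_by_deletion(reads, PARAMS), peaks)
        t_then_d = filter_by_deletion(filter_by_tss(reads, peaks), PARAMS)
        assert d_then_t == t_then_d
        assert filter_by_deletion(d_then_t, PARAMS) == d_then_t
        assert filter_by_tss(d_then_t, peaks) == d_then_t


class TestCollapse:
    def chain_reads(self, n, chain=((200, 300),), starts=None, ends=None, strand="+"):
        starts = starts or [100] * n
        ends = ends or [400] * n
        reads = []
        for i in range(n):
            bounds = [starts[i]]
            for d, a in chain:
                bounds.extend((d, a))
            bounds.append(ends[i])
            blocks = tuple(
                (bounds[k], bounds[k + 1]) for k in range(0, len(bounds), 2)
            )
            reads.append(SplicedRead(f"r{i}", "chr1", strand, blocks))
        return correct_reads(reads, self.true_table(chain, strand), PARAMS)

    def true_table(self, chain, strand="+"):
        t = JunctionTable()
        for d, a in chain:
            t.add("chr1", d, a, strand, 10)
        return t

    def test_median_start(self):
        corrected = self.chain_reads(5, starts=[1000, 1001, 999, 1000, 1000],
                                     chain=((1200, 1300),),
                                     ends=[1500] * 5)
        ann, support = collapse_reads(corrected, PARAMS)
        assert len(ann) == 1
        t = next(iter(ann))
        assert t.start == 1000
        assert support[t.transcript_id] == 5

    def test_below_support_threshold_dropped(self):
        ann, _ = collapse_reads(self.chain_reads(2), PARAMS)
        assert len(ann) == 0

    def test_two_chains_one_gene(self):
        a = self.chain_reads(3, chain=((200, 300),))
        b = self.chain_reads(3, chain=((200, 350),))
        ann, _ = collapse_reads(a + b, PARAMS)
        assert len(ann) == 2
        genes = {t.gene_id for t in ann}
        assert len(genes) == 1

    def test_chains_on_different_strands_not_merged(self):
        a = self.chain_reads(3, chain=((200, 300),), strand="+")
        b = self.chain_reads(3, chain=((200, 300),), strand="-")
        ann, _ = collapse_reads(a + b, PARAMS)
        assert len(ann) == 2
        assert len({t.gene_id for t in ann}) == 2

    def test_single_exon_reciprocal_overlap_grouping(self):
        reads = [
            SplicedRead(f"r{i}", "chr1", "+", ((100 + i, 400 + i),))
            for i in range(4)
        ] + [SplicedRead("far", "chr1", "+", ((10_000, 10_300),))]
        corrected = correct_reads(reads, JunctionTable(), PARAMS)
        ann, support = collapse_reads(corrected, PARAMS)
        assert len(ann) == 1  # the singleton lacks support
        assert list(support.values()) == [4]

    def test_rejected_reads_refused(self):
        t = JunctionTable()
        read = SplicedRead("r", "chr1", "+", ((100, 200), (300, 400)))
        rejected = correct_read(read, t, PARAMS)
        with pytest.raises(ValueError):
            collapse_reads([rejected], PARAMS)

    def test_empty_input_empty_annotation(self):
        ann, support = collapse_reads([], PARAMS)
        assert len(ann) == 0 and support == {}

    def test_deterministic_uuid_style_ids(self):
        ann1, _ = collapse_reads(self.chain_reads(3), PARAMS)
        ann2, _ = collapse_reads(self.chain_reads(3), PARAMS)
        assert set(ann1.transcripts) == set(ann2.transcripts)
        tid = next(iter(ann1.transcripts))
        assert len(tid.split("-")) == 5  # uuid-style


class TestTruthRecovery:
    def test_jittered_reads_recover_true_chains(self, small_sim):
        """With jitter bounded by the correction window and true junctions
        supported, every non-rejected read recovers its true chain."""
        cfg, paths, truth = small_sim
        junctions = read_junctions(paths["junctions"])
        true_chains = {
            t.transcript_id: t.intron_chain for t in truth.annotation
        }
        n_checked = 0
        for sample in cfg.samples:
            for read in read_reads(paths[f"reads_{sample}"]):
                c = correct_read(read, junctions, PARAMS)
                assert c.status != "rejected"
                tid, _ = truth.read_origin[read.read_id]
                assert c.corrected_junctions == true_chains[tid]
                n_checked += 1
        assert n_checked == len(truth.read_origin)

    def test_noiseless_collapse_reproduces_truth_chains(self, clean_sim):
        cfg, paths, truth = clean_sim
        reads = [
            r
            for s in cfg.samples
            for r in read_reads(paths[f"reads_{s}"])
        ]
        ann, _, log = refine(
            reads,
            read_junctions(paths["junctions"]),
            read_peaks(paths["peaks"]),
        )
        assert log["removed_deletion"] == 0
        assert log["removed_correction"] == 0
        assert ann.chain_keys() == truth.annotation.chain_keys()
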