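"""Shared fixtures: hand-built miniature annotations and a session-scoped
synthetic dataset."""

import pytest

from isoformatlas.formats_io import (
    Annotation,
    GenomicInterval,
    TranscriptModel,
)
from isoformatlas.synthetic_data import SimConfig, simulate


def make_transcript(
    tid,
    gene,
    exons,
    chrom="chr1",
    strand="+",
    cds=None,
):
    """Build a TranscriptModel from (start, end) exon tuples."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        cds=tuple(GenomicInterval(chrom, s, e, strand) for s, e in cds)
        if cds
        else None,
    )


@pytest.fixture
def two_gene_annotation():
    """Two genes: geneA with three isoforms of a 4-exon locus (full chain,
    one exon-skip, one intron-retention), geneB single-isoform."""
    e = [(100, 200), (300, 400), (500, 600), (700, 800)]
    t0 = make_transcript("tA0", "geneA", e)
    t1 = make_transcript("tA1", "geneA", [e[0], e[2], e[3]])  # skips exon 1
    t2 = make_transcript("tA2", "geneA", [(100, 400), e[2], e[3]])  # retains intron 0
    tb = make_transcript("tB0", "geneB", [(2000, 2200), (2400, 2600)])
    return Annotation.from_transcripts([t0, t1, t2, tb])


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small (20-gene) simulated dataset shared across tests."""
    cfg = SimConfig(n_genes=20, seed=11)
    out = tmp_path_factory.mktemp("sim")
    paths, truth = simulate(cfg, out)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Noise-free simulation: no jitter, truncation, long deletions, or low
    mapq; used by bookkeeping and exact-recovery tests."""
    cfg = SimConfig(
        n_genes=15,
        seed=5,
        junction_jitter_sd=0.0,
        tss_truncation_prob=0.0,
        long_deletion_prob=0.0,
        mapq_zero_prob=0.0,
        mapq_low_prob=0.0,
        deletion_mean=0.0,
    )
    out = tmp_path_factory.mktemp("clean_sim")
    paths, truth = simulate(cfg, out)
    return cfg, paths, truth
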