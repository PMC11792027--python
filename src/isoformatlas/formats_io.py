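"""Readers and writers for the on-disk formats used throughout the package.

All in-memory coordinates are 0-based half-open (BED-like).  GTF is the only
1-based closed format and is converted at this boundary, so no ±1 arithmetic
appears in analysis code.  Every reader is gzip-transparent (a ``.gz`` suffix
switches to :mod:`gzip`).

Formats
-------
* GTF 2.2, GENCODE attribute dialect (``gene_id "..."; transcript_id "...";``)
  with ``exon`` and optional ``CDS`` features.
* BED6 for open-chromatin (ATAC) peaks.
* FASTA for genome sequences (via Biopython; sequences are upper-cased).
* A neutral tab-separated long-read dialect (one row per spliced read with
  comma-joined block starts/ends) standing in for BAM.
* A junction table (chrom, donor, acceptor, strand, unique-read support).
"""

from __future__ import annotations

import gzip
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from intervaltree import IntervalTree

STRANDS = frozenset({"+", "-", "."})


class ParseError(ValueError):
    """Malformed record in an input file; the message names the line."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A strand-aware exon chain; the unit of annotation and quantification.

    ``exons`` are ascending, disjoint intervals on one chromosome/strand.
    ``cds`` (optional) holds the genomic CDS pieces, from which the
    5'UTR/CDS/3'UTR partition in transcript coordinates is derived.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on wrong chrom"
                )
        if self.cds is not None:
            self.cds = tuple(sorted(self.cds, key=lambda e: e.start))
            for c in self.cds:
                if not any(
                    e.start <= c.start and c.end <= e.end for e in self.exons
                ):
                    raise ValueError(
                        f"transcript {self.transcript_id}: CDS outside exons"
                    )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) pairs in genomic coordinates."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def chain_key(self) -> tuple:
        """Identity key used for isoform matching across annotations."""
        return (self.chrom, self.strand, self.intron_chain)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to a 0-based offset along the spliced
        transcript (5' -> 3'); ``None`` if the position is intronic/outside."""
        off = 0
        for e in self.exons:
            if e.contains(pos):
                plus = off + (pos - e.start)
                if self.strand == "+":
                    return plus
                return self.spliced_length - 1 - plus
            off += len(e)
        return None

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced sense-strand sequence."""
        seq = "".join(genome[self.chrom][e.start:e.end] for e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def utr_cds_lengths(self) -> tuple[int, int, int] | None:
        """(5'UTR, CDS, 3'UTR) spliced lengths, or None without a CDS."""
        if not self.cds:
            return None
        cds_len = sum(len(c) for c in self.cds)
        first = self.cds[0].start if self.strand == "+" else self.cds[-1].end - 1
        tpos = self.genomic_to_transcript(first)
        assert tpos is not None
        utr5 = tpos
        utr3 = self.spliced_length - utr5 - cds_len
        return utr5, cds_len, utr3


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Annotation:
    """A set of transcripts grouped into genes."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @property
    def genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for t in self.transcripts.values():
            out.setdefault(t.gene_id, set()).add(t.transcript_id)
        return out

    @classmethod
    def from_transcripts(cls, txs: Iterable[TranscriptModel]) -> "Annotation":
        d: dict[str, TranscriptModel] = {}
        for t in txs:
            if t.transcript_id in d:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            d[t.transcript_id] = t
        return cls(d)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def chain_keys(self) -> set[tuple]:
        return {t.chain_key() for t in self}


@dataclass
class SplicedRead:
    """One aligned long read: exon blocks plus alignment-level metadata."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    total_deletion: int = 0
    mapq: int = 60
    polya_length: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: strand must be + or -")
        if self.total_deletion < 0 or self.mapq < 0:
            raise ValueError(f"read {self.read_id}: negative field")
        blocks = tuple(tuple(b) for b in self.blocks)
        for s, e in blocks:
            if not (0 <= s < e):
                raise ValueError(f"read {self.read_id}: bad block {s}-{e}")
        for (_, e1), (s2, _) in zip(blocks, blocks[1:]):
            if e1 > s2:
                raise ValueError(f"read {self.read_id}: blocks not disjoint")
        self.blocks = blocks

    @property
    def five_prime_pos(self) -> int:
        if self.strand == "+":
            return self.blocks[0][0]
        return self.blocks[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])
        )

    def chain_key(self) -> tuple:
        return (self.chrom, self.strand, self.junctions)


class JunctionTable:
    """Short-read splice junctions with unique-read support counts.

    Supports window queries used by splice-site correction: all junctions on
    a chromosome strand whose donor and acceptor both fall within ±window of
    a query junction.
    """

    def __init__(self, support: Mapping[tuple[str, int, int, str], int] | None = None):
        self.support: dict[tuple[str, int, int, str], int] = {}
        if support:
            for key, n in support.items():
                self.add(*key, n)
        self._index: dict[tuple[str, str], tuple[list[int], list[tuple[int, int, int]]]] | None = None

    def add(self, chrom: str, donor: int, acceptor: int, strand: str, n: int) -> None:
        if donor >= acceptor:
            raise ValueError(f"junction donor {donor} >= acceptor {acceptor}")
        if n < 0:
            raise ValueError("negative junction support")
        self.support[(chrom, donor, acceptor, strand)] = (
            self.support.get((chrom, donor, acceptor, strand), 0) + n
        )
        self._index = None

    def __len__(self) -> int:
        return len(self.support)

    def filtered(self, min_support: int) -> "JunctionTable":
        return JunctionTable(
            {k: n for k, n in self.support.items() if n >= min_support}
        )

    def _build_index(self):
        idx: dict[tuple[str, str], tuple[list[int], list[tuple[int, int, int]]]] = {}
        grouped: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for (chrom, d, a, strand), n in self.support.items():
            grouped.setdefault((chrom, strand), []).append((d, a, n))
        for key, rows in grouped.items():
            rows.sort()
            idx[key] = ([r[0] for r in rows], rows)
        self._index = idx

    def candidates(
        self, chrom: str, strand: str, donor: int, acceptor: int, window: int
    ) -> list[tuple[int, int, int]]:
        """(donor, acceptor, support) rows with both ends within ±window."""
        if self._index is None:
            self._build_index()
        entry = self._index.get((chrom, strand))
        if entry is None:
            return []
        donors, rows = entry
        lo = bisect_left(donors, donor - window)
        hi = bisect_right(donors, donor + window)
        return [
            (d, a, n)
            for d, a, n in rows[lo:hi]
            if abs(a - acceptor) <= window
        ]


class PeakSet:
    """Open-chromatin peaks with point-overlap queries per chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):  # noqa: B008
        self._trees: dict[str, IntervalTree] = {}
        self.intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self.intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def query(self, chrom: str, pos: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]

    def contains_point(self, chrom: str, pos: int) -> bool:
        return bool(self.query(chrom, pos))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path) -> Annotation:
    """Read a GENCODE-dialect GTF into an :class:`Annotation`.

    Only ``exon`` and ``CDS`` features are consumed; 1-based closed
    coordinates are converted to 0-based half-open here and nowhere else.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ParseError(f"line {lineno}: end < start")
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attrs_s)
            try:
                tid, gid = attrs["transcript_id"], attrs["gene_id"]
            except KeyError as exc:
                raise ParseError(
                    f"line {lineno}: missing required attribute {exc}"
                ) from exc
            prev_gene = gene_of.setdefault(tid, gid)
            if prev_gene != gid:
                raise ParseError(
                    f"line {lineno}: transcript {tid} in two genes"
                )
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    txs = []
    for tid, ex in exons.items():
        txs.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of[tid],
                chrom=ex[0].chrom,
                strand=ex[0].strand,
                exons=tuple(ex),
                cds=tuple(cds[tid]) if tid in cds else None,
            )
        )
    return Annotation.from_transcripts(txs)


def write_gtf(annotation: Annotation, path) -> None:
    """Write an :class:`Annotation` as GENCODE-dialect GTF (1-based closed)."""
    with _open_text(path, "wt") as fh:
        fh.write("##format: gtf\n")
        for gid in sorted(annotation.genes):
            for tid in sorted(annotation.genes[gid]):
                t = annotation.transcripts[tid]
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                fh.write(
                    f"{t.chrom}\tisoformatlas\ttranscript\t{t.start + 1}\t"
                    f"{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{t.chrom}\tisoformatlas\texon\t{e.start + 1}\t"
                        f"{e.end}\t.\t{t.strand}\t.\t{attrs}\n"
                    )
                for c in t.cds or ():
                    fh.write(
                        f"{t.chrom}\tisoformatlas\tCDS\t{c.start + 1}\t"
                        f"{c.end}\t.\t{t.strand}\t0\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Reads TSV
# ---------------------------------------------------------------------------

_READS_COLUMNS = (
    "read_id",
    "chrom",
    "strand",
    "block_starts",
    "block_ends",
    "total_deletion",
    "mapq",
    "polya_length",
)


def read_reads(path) -> list[SplicedRead]:
    """Read the neutral tab-separated spliced-read dialect."""
    reads: list[SplicedRead] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_READS_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(_READS_COLUMNS)} fields"
                )
            rid, chrom, strand, starts_s, ends_s, dele_s, mapq_s, tail_s = fields
            try:
                starts = [int(x) for x in starts_s.split(",") if x != ""]
                ends = [int(x) for x in ends_s.split(",") if x != ""]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer block") from exc
            if len(starts) != len(ends) or not starts:
                raise ParseError(f"line {lineno}: ragged block lists")
            try:
                read = SplicedRead(
                    read_id=rid,
                    chrom=chrom,
                    strand=strand,
                    blocks=tuple(zip(starts, ends)),
                    total_deletion=int(dele_s),
                    mapq=int(mapq_s),
                    polya_length=float(tail_s) if tail_s != "" else None,
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            reads.append(read)
    return reads


def write_reads(reads: Iterable[SplicedRead], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(_READS_COLUMNS) + "\n")
        for r in reads:
            starts = ",".join(str(s) for s, _ in r.blocks)
            ends = ",".join(str(e) for _, e in r.blocks)
            tail = "" if r.polya_length is None else f"{r.polya_length:.2f}"
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.strand}\t{starts}\t{ends}\t"
                f"{r.total_deletion}\t{r.mapq}\t{tail}\n"
            )


# ---------------------------------------------------------------------------
# Junctions, peaks, FASTA
# ---------------------------------------------------------------------------

def read_junctions(path) -> JunctionTable:
    table = JunctionTable()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 5 fields")
            chrom, donor_s, acceptor_s, strand, n_s = fields
            try:
                table.add(chrom, int(donor_s), int(acceptor_s), strand, int(n_s))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return table


def write_junctions(table: JunctionTable, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#chrom\tdonor\tacceptor\tstrand\tunique_reads\n")
        for (chrom, d, a, strand), n in sorted(table.support.items()):
            fh.write(f"{chrom}\t{d}\t{a}\t{strand}\t{n}\n")


def read_peaks(path) -> PeakSet:
    """Read a BED6 (or BED3) peak file; coordinates are native 0-based."""
    peaks = PeakSet()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >=3 BED fields")
            chrom, start_s, end_s = fields[:3]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                peaks.add(GenomicInterval(chrom, int(start_s), int(end_s), strand))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: PeakSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(sorted(peaks.intervals)):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t0\t{iv.strand}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read FASTA; sequences are upper-cased."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
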