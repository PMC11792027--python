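"""Classification of de-novo transcripts against a reference annotation.

Implements a GffCompare-style class-code scheme reduced to the codes that a
splice-aware comparison can assign natively:

========  =============================================================
code      meaning
========  =============================================================
``=``     exact intron-chain match (single-exon: overlapping exon)
``c``     query chain is a contiguous sub-chain of the reference
``k``     reference chain is a contiguous sub-chain of the query
``j``     at least one shared junction, but chains differ
``e``     single-exon query overlapping a reference exon
``i``     query fully contained within a reference intron
``o``     other same-strand exonic overlap
``x``     opposite-strand exonic overlap
``u``     no exonic overlap with any reference transcript (novel gene)
========  =============================================================

The rare fuzzy codes ``m, n, s, p, r, y`` are accepted on input and mapped
to their categories but are never emitted.  The three downstream categories
are fixed: ``=`` -> matched; ``m j o x i y u`` -> different;
``c k n e s p r`` -> others.

The module also derives tissue-specific transcripts (intron-chain identity
across tissues), per-gene dominant transcripts, and a longest-ORF coding
stand-in for transcript peptide prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import Annotation, TranscriptModel

MATCHED_CODES = frozenset("=")
DIFFERENT_CODES = frozenset("mjoxiyu")
OTHERS_CODES = frozenset("cknespr")
ALL_CODES = MATCHED_CODES | DIFFERENT_CODES | OTHERS_CODES

#: emission priority (best first) of natively computed codes
CODE_PRIORITY = ("=", "c", "k", "j", "e", "i", "o", "x")


def category_of(code: str) -> str:
    if code in MATCHED_CODES:
        return "matched"
    if code in DIFFERENT_CODES:
        return "different"
    if code in OTHERS_CODES:
        return "others"
    raise ValueError(f"unknown class code {code!r}")


@dataclass(frozen=True)
class ClassAssignment:
    query_id: str
    ref_id: str | None
    code: str
    category: str

    @property
    def novel_gene(self) -> bool:
        return self.code == "u"


# ---------------------------------------------------------------------------
# class codes
# ---------------------------------------------------------------------------

def _exonic_overlap_bp(q: TranscriptModel, r: TranscriptModel) -> int:
    total = 0
    for qe in q.exons:
        for re_ in r.exons:
            total += max(0, min(qe.end, re_.end) - max(qe.start, re_.start))
    return total


def _is_contiguous_subchain(sub: tuple, full: tuple) -> bool:
    """True if ``sub`` equals a contiguous run of ``full`` (proper subset)."""
    n, m = len(sub), len(full)
    if n == 0 or n >= m:
        return False
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def _within_ref_intron(q: TranscriptModel, r: TranscriptModel) -> bool:
    return any(d <= q.start and q.end <= a for d, a in r.intron_chain)


def _pair_code(q: TranscriptModel, r: TranscriptModel) -> str | None:
    """Class code of query vs one reference transcript, or None when the two
    are unrelated (span overlap without any qualifying relation)."""
    overlap = _exonic_overlap_bp(q, r)
    if q.strand != r.strand:
        return "x" if overlap > 0 else None
    qc, rc = q.intron_chain, r.intron_chain
    if qc == rc and (qc or overlap > 0):
        return "="
    if _is_contiguous_subchain(qc, rc):
        return "c"
    if _is_contiguous_subchain(rc, qc):
        return "k"
    if qc and rc and set(qc) & set(rc):
        return "j"
    if not qc and overlap > 0:
        return "e"
    if _within_ref_intron(q, r):
        return "i"
    if overlap > 0:
        return "o"
    return None


def assign_class_codes(
    query: Annotation, reference: Annotation
) -> list[ClassAssignment]:
    """Assign a class code and category to every query transcript.

    The best reference match is the one with the highest code priority,
    then the longest exonic overlap, then the lexicographically smallest
    reference id (deterministic).  Queries with no qualifying reference
    relation on either strand receive ``u`` (novel gene).
    """
    trees: dict[str, IntervalTree] = {}
    for t in reference:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)

    rank = {code: i for i, code in enumerate(CODE_PRIORITY)}
    out: list[ClassAssignment] = []
    for qid in sorted(query.transcripts):
        q = query.transcripts[qid]
        best: tuple[int, int, str] | None = None  # (rank, -overlap, ref_id)
        tree = trees.get(q.chrom)
        for hit in tree.overlap(q.start, q.end) if tree is not None else ():
            r = hit.data
            code = _pair_code(q, r)
            if code is None:
                continue
            cand = (rank[code], -_exonic_overlap_bp(q, r), r.transcript_id)
            if best is None or cand < best:
                best = cand
        if best is None:
            out.append(ClassAssignment(qid, None, "u", category_of("u")))
        else:
            code = CODE_PRIORITY[best[0]]
            out.append(ClassAssignment(qid, best[2], code, category_of(code)))
    return out


def assignments_frame(assignments: Iterable[ClassAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "ref_id": a.ref_id,
                "code": a.code,
                "category": a.category,
                "novel_gene": a.novel_gene,
            }
            for a in assignments
        ]
    )


# ---------------------------------------------------------------------------
# tissue-specific / dominant transcripts
# ---------------------------------------------------------------------------

def find_tissue_specific(
    tissue_sets: Mapping[str, Annotation]
) -> dict[str, set[tuple]]:
    """Transcripts (keyed by chrom/strand/intron chain) present in exactly
    one tissue's annotation.  Requires at least two tissues."""
    if len(tissue_sets) < 2:
        raise ValueError("tissue-specific comparison needs >= 2 tissues")
    keys_by_tissue = {
        tissue: ann.chain_keys() for tissue, ann in tissue_sets.items()
    }
    out: dict[str, set[tuple]] = {}
    for tissue, keys in keys_by_tissue.items():
        others: set[tuple] = set()
        for other, okeys in keys_by_tissue.items():
            if other != tissue:
                others |= okeys
        out[tissue] = keys - others
    return out


def find_dominant(
    annotation: Annotation,
    counts: pd.DataFrame,
    condition_samples: Iterable[str],
) -> dict[str, str]:
    """Per gene, the most highly expressed transcript (summed counts over
    the condition's samples); ties break to the lexicographically smaller
    transcript id; all-zero genes are omitted."""
    cols = [c for c in condition_samples if c in counts.columns]
    totals = counts[cols].sum(axis=1)
    out: dict[str, str] = {}
    for gid, tids in annotation.genes.items():
        present = sorted(t for t in tids if t in totals.index)
        if not present:
            continue
        # ties resolve to the smallest id: iterate sorted ids, keep strict >
        best = present[0]
        for t in present[1:]:
            if totals[t] > totals[best]:
                best = t
        if totals[best] > 0:
            out[gid] = best
    return out


# ---------------------------------------------------------------------------
# longest ORF
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = None


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).translate())


def longest_orf(transcript_sequence: str) -> tuple[int, str]:
    """Longest ATG-initiated ORF ending at an in-frame stop fully inside the
    sense-strand sequence.  Returns (protein length excluding the stop,
    protein sequence); (0, "") when no complete ORF exists.  Ties break to
    the 5'-most start.
    """
    seq = transcript_sequence.upper()
    n = len(seq)
    # per frame: sorted positions of stop codons
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n - 2):
        if seq[i : i + 3] in _STOPS:
            stops_by_frame[i % 3].append(i)
    from bisect import bisect_left

    best_len = 0
    best_start = -1
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        stops = stops_by_frame[i % 3]
        j = bisect_left(stops, i + 3)
        if j == len(stops):
            continue
        aa_len = (stops[j] - i) // 3
        if aa_len > best_len:
            best_len = aa_len
            best_start = i
    if best_len == 0:
        return 0, ""
    cds = seq[best_start : best_start + 3 * best_len]
    return best_len, _translate(cds)
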