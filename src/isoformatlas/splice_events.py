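"""Alternative-splicing event enumeration and differential testing.

Events are derived from pairwise comparison of isoforms within a gene and
quantified through full-length transcript assignments (the long-read
advantage), not junction-spanning short reads.  Seven event types are
enumerated, unifying the FLAIR diffSplice set (ES, IR, ALT5, ALT3) with the
SUPPA2 extensions (AF, AL, MX):

* ES   — exon(s) present between two shared junction anchors in one chain
         and skipped by a single junction in another; one event per
         contiguous skipped block between the same anchors.
* IR   — one chain's intron fully contained inside another chain's exon.
* ALT5 — junctions sharing one end, differing at the 5'-splice-site end
         (strand-aware); ALT3 analogously at the 3' end.
* AF   — distinct, non-overlapping first exons with the remaining chain
         identical; AL analogously for last exons (strand-aware).
* MX   — two non-overlapping internal exons, each used exclusively between
         the same pair of flanking anchors.

Inclusion and exclusion transcript sets are recomputed over *all* isoforms
of the gene matching the event's defining junction pattern, and events are
deduplicated by (type, coordinates).  Differences between conditions are
tested per event with a two-sided Fisher's exact test on pooled
inclusion/exclusion counts; PSI = inclusion / (inclusion + exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .formats_io import Annotation, TranscriptModel
from .quant_diff import CountsMatrix, fisher_exact_two_sided

EVENT_TYPES = ("ES", "IR", "ALT3", "ALT5", "AF", "AL", "MX")


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    type: str
    gene_id: str
    chrom: str
    strand: str
    coordinates: tuple[int, ...]
    inclusion: frozenset[str]
    exclusion: frozenset[str]

    def __post_init__(self) -> None:
        if self.inclusion & self.exclusion:
            raise ValueError("inclusion and exclusion sets overlap")
        if not self.inclusion or not self.exclusion:
            raise ValueError("inclusion and exclusion must be non-empty")


def _event_id(etype: str, chrom: str, strand: str, coords: tuple[int, ...]) -> str:
    return f"{etype}:{chrom}:{strand}:" + "-".join(str(c) for c in coords)


def _first_exon(t: TranscriptModel) -> tuple[int, int]:
    return (t.start, t.intron_chain[0][0])


def _last_exon(t: TranscriptModel) -> tuple[int, int]:
    return (t.intron_chain[-1][1], t.end)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def enumerate_events(annotation: Annotation) -> list[ASEvent]:
    """Enumerate AS events across all multi-isoform genes, deduplicated by
    (type, coordinates); deterministic output order."""
    events: dict[str, ASEvent] = {}
    genes = annotation.genes
    for gid in sorted(genes):
        txs = [annotation.transcripts[t] for t in sorted(genes[gid])]
        if len(txs) < 2:
            continue
        for ev in _gene_events(gid, txs):
            events.setdefault(ev.event_id, ev)
    return [events[k] for k in sorted(events)]


def _gene_events(gid: str, txs: list[TranscriptModel]) -> Iterable[ASEvent]:
    chrom, strand = txs[0].chrom, txs[0].strand
    chains = {t.transcript_id: t.intron_chain for t in txs}
    jsets = {tid: set(c) for tid, c in chains.items()}

    def ids_with_junctions(*juncs) -> frozenset[str]:
        return frozenset(
            tid for tid, js in jsets.items() if all(j in js for j in juncs)
        )

    def ids_with_consecutive(j1, j2) -> frozenset[str]:
        out = set()
        for tid, c in chains.items():
            for k in range(len(c) - 1):
                if c[k] == j1 and c[k + 1] == j2:
                    out.add(tid)
                    break
        return frozenset(out)

    # exon lookup: does any transcript with a given junction have an exon
    # extending across the alternative boundary (distinguishes a true
    # alternative splice site from an exon-skipping junction pair)?
    exons_of = {t.transcript_id: [(e.start, e.end) for e in t.exons] for t in txs}

    def exon_starting_at(tid: str, start: int) -> tuple[int, int] | None:
        for s, e in exons_of[tid]:
            if s == start:
                return (s, e)
        return None

    def exon_ending_at(tid: str, end: int) -> tuple[int, int] | None:
        for s, e in exons_of[tid]:
            if e == end:
                return (s, e)
        return None

    seen: set[tuple] = set()
    for t1, t2 in combinations(txs, 2):
        c1, c2 = t1.intron_chain, t2.intron_chain
        # --- ES: skip junction (d, a) in one chain vs exon path in the other
        for incl, excl in ((t1, t2), (t2, t1)):
            ci, ce = incl.intron_chain, excl.intron_chain
            for d, a in ce:
                left = [j for j in ci if j[0] == d and j[1] < a]
                right = [j for j in ci if j[1] == a and j[0] > d]
                for _, a1 in left:
                    for d2, _ in right:
                        if a1 >= d2:
                            continue
                        coords = (d, a1, d2, a)
                        key = ("ES", coords)
                        if key in seen:
                            continue
                        seen.add(key)
                        inc = ids_with_junctions((d, a1), (d2, a))
                        exc = ids_with_junctions((d, a))
                        ev = _make(gid, chrom, strand, "ES", coords, inc, exc)
                        if ev:
                            yield ev
        # --- IR: intron of one inside exon of the other
        for retainer, splicer in ((t1, t2), (t2, t1)):
            for d, a in splicer.intron_chain:
                for e in retainer.exons:
                    if e.start < d and a < e.end:
                        coords = (d, a)
                        key = ("IR", coords)
                        if key in seen:
                            break
                        seen.add(key)
                        inc = frozenset(
                            t.transcript_id
                            for t in txs
                            if any(
                                x.start < d and a < x.end for x in t.exons
                            )
                        )
                        exc = ids_with_junctions((d, a))
                        ev = _make(gid, chrom, strand, "IR", coords, inc, exc)
                        if ev:
                            yield ev
                        break
        # --- ALT5/ALT3: shared end, differing other end
        for j1 in c1:
            for j2 in c2:
                if j1 == j2:
                    continue
                if j1[1] == j2[1] and j1[0] != j2[0]:
                    # differing left (genomic) end: a true alternative donor
                    # only if the exon ending at the longer-exon boundary
                    # spans the other boundary (otherwise this junction pair
                    # reflects exon skipping, handled by ES)
                    etype = "ALT5" if strand == "+" else "ALT3"
                    dmin, dmax = sorted((j1[0], j2[0]))
                    coords = (dmin, dmax, j1[1])
                    key = (etype, coords)
                    if key in seen:
                        continue
                    seen.add(key)
                    inc = ids_with_junctions((dmax, j1[1]))  # shorter intron
                    exc = ids_with_junctions((dmin, j1[1]))
                    if not any(
                        (ex := exon_ending_at(tid, dmax)) and ex[0] < dmin
                        for tid in inc
                    ):
                        continue
                    ev = _make(gid, chrom, strand, etype, coords, inc, exc)
                    if ev:
                        yield ev
                elif j1[0] == j2[0] and j1[1] != j2[1]:
                    etype = "ALT3" if strand == "+" else "ALT5"
                    amin, amax = sorted((j1[1], j2[1]))
                    coords = (j1[0], amin, amax)
                    key = (etype, coords)
                    if key in seen:
                        continue
                    seen.add(key)
                    inc = ids_with_junctions((j1[0], amin))  # shorter intron
                    exc = ids_with_junctions((j1[0], amax))
                    if not any(
                        (ex := exon_starting_at(tid, amin)) and ex[1] > amax
                        for tid in inc
                    ):
                        continue
                    ev = _make(gid, chrom, strand, etype, coords, inc, exc)
                    if ev:
                        yield ev
        # --- AF/AL: distinct non-overlapping terminal exons, rest identical
        if c1 and c2 and len(c1) == len(c2):
            if (
                c1[0] != c2[0]
                and c1[1:] == c2[1:]
                and not _overlaps(_first_exon(t1), _first_exon(t2))
            ):
                etype = "AF" if strand == "+" else "AL"
                v1, v2 = sorted((c1[0], c2[0]))
                coords = (*v1, *v2)
                key = (etype, coords, c1[1:])
                if key not in seen:
                    seen.add(key)
                    rest = c1[1:]
                    inc = frozenset(
                        tid
                        for tid, c in chains.items()
                        if c and c[0] == v1 and c[1:] == rest
                    )
                    exc = frozenset(
                        tid
                        for tid, c in chains.items()
                        if c and c[0] == v2 and c[1:] == rest
                    )
                    ev = _make(gid, chrom, strand, etype, coords, inc, exc)
                    if ev:
                        yield ev
            if (
                c1[-1] != c2[-1]
                and c1[:-1] == c2[:-1]
                and not _overlaps(_last_exon(t1), _last_exon(t2))
            ):
                etype = "AL" if strand == "+" else "AF"
                v1, v2 = sorted((c1[-1], c2[-1]))
                coords = (*v1, *v2)
                key = (etype, coords, c1[:-1])
                if key not in seen:
                    seen.add(key)
                    rest = c1[:-1]
                    inc = frozenset(
                        tid
                        for tid, c in chains.items()
                        if c and c[-1] == v1 and c[:-1] == rest
                    )
                    exc = frozenset(
                        tid
                        for tid, c in chains.items()
                        if c and c[-1] == v2 and c[:-1] == rest
                    )
                    ev = _make(gid, chrom, strand, etype, coords, inc, exc)
                    if ev:
                        yield ev
        # --- MX: mutually exclusive internal exons between shared anchors
        for k1 in range(len(c1) - 1):
            (d, a1), (d1, a) = c1[k1], c1[k1 + 1]
            for k2 in range(len(c2) - 1):
                (dd, a2), (d2, aa) = c2[k2], c2[k2 + 1]
                if dd != d or aa != a:
                    continue
                e1, e2 = (a1, d1), (a2, d2)
                if e1 == e2 or _overlaps(e1, e2):
                    continue
                emin, emax = sorted((e1, e2))
                coords = (d, *emin, *emax, a)
                key = ("MX", coords)
                if key in seen:
                    continue
                seen.add(key)
                inc = ids_with_consecutive((d, emin[0]), (emin[1], a))
                exc = ids_with_consecutive((d, emax[0]), (emax[1], a))
                ev = _make(gid, chrom, strand, "MX", coords, inc, exc)
                if ev:
                    yield ev


def _make(gid, chrom, strand, etype, coords, inc, exc) -> ASEvent | None:
    inc, exc = frozenset(inc), frozenset(exc)
    overlap = inc & exc
    inc, exc = inc - overlap, exc - overlap
    if not inc or not exc:
        return None
    return ASEvent(
        event_id=_event_id(etype, chrom, strand, coords),
        type=etype,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        coordinates=tuple(coords),
        inclusion=inc,
        exclusion=exc,
    )


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------

def test_events(
    events: Iterable[ASEvent],
    counts: CountsMatrix,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fisher's exact test on [incl_A, excl_A; incl_B, excl_B] per event.

    PSI is reported per condition (NaN when the condition total is zero, in
    which case p = 1 and the event is marked untestable).  ``significant``
    requires p < alpha (strict).
    """
    a = counts.pooled(cond_a)
    b = counts.pooled(cond_b)

    def total(series: pd.Series, ids: frozenset[str]) -> int:
        return int(series.reindex(sorted(ids), fill_value=0).sum())

    rows = []
    for ev in events:
        ia, xa = total(a, ev.inclusion), total(a, ev.exclusion)
        ib, xb = total(b, ev.inclusion), total(b, ev.exclusion)
        testable = (ia + xa) > 0 and (ib + xb) > 0
        psi_a = ia / (ia + xa) if (ia + xa) > 0 else np.nan
        psi_b = ib / (ib + xb) if (ib + xb) > 0 else np.nan
        p = (
            fisher_exact_two_sided(np.array([[ia, xa], [ib, xb]]))
            if testable
            else 1.0
        )
        rows.append(
            {
                "event_id": ev.event_id,
                "type": ev.type,
                "gene_id": ev.gene_id,
                "psi_a": psi_a,
                "psi_b": psi_b,
                "delta_psi": psi_b - psi_a if testable else np.nan,
                "p_value": p,
                "testable": testable,
                "significant": testable and p < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "type",
            "gene_id",
            "psi_a",
            "psi_b",
            "delta_psi",
            "p_value",
            "testable",
            "significant",
        ],
    )
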