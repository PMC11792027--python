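"""DRACH-site discovery, filtering, differential m6A testing, and metagene
positioning.

The m6A layer is count-based: each candidate site carries per-sample
(modified, total) read counts; signal-level inference is out of scope and
the counts are the input contract.  Candidate sites are every adenosine at
position 3 of a DRACH motif (D = A/G/T, R = A/G, then A, C, H = A/C/T)
within the exonic sequence of any transcript, on both strands.  Sites are
filtered for coverage (total >= 5 reads in at least 2 samples) and
recurrence (modified > 0 in at least 2 samples), tested between conditions
with Fisher's exact test on pooled modified/unmodified counts
(|log2FC of modification frequency| > 0.5 and p < 0.01, both strict), and
positioned on a metagene axis where the 5'UTR maps to [0,1), the CDS to
[1,2) and the 3'UTR to [2,3].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .formats_io import Annotation, reverse_complement
from .quant_diff import fisher_exact_two_sided

_D = frozenset("AGT")
_R = frozenset("AG")
_H = frozenset("ACT")


def is_drach(motif: str) -> bool:
    if len(motif) != 5:
        return False
    m = motif.upper()
    return (
        m[0] in _D and m[1] in _R and m[2] == "A" and m[3] == "C" and m[4] in _H
    )


@dataclass
class M6ASite:
    chrom: str
    position: int  # the A, 0-based genomic
    strand: str
    motif: str
    region: tuple[int, int]
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    # counts: sample -> (modified, total)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.position}:{self.strand}"

    def __post_init__(self) -> None:
        for sample, (mod, tot) in self.counts.items():
            if mod < 0 or mod > tot:
                raise ValueError(
                    f"site {self.key} sample {sample}: modified > total"
                )


@dataclass(frozen=True)
class MetagenePosition:
    site_key: str
    transcript_id: str
    segment: str  # 5UTR | CDS | 3UTR
    relative: float  # in [0, 3]


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _merged_exonic_intervals(annotation: Annotation):
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for t in annotation:
        for e in t.exons:
            by_key.setdefault((t.chrom, t.strand), []).append((e.start, e.end))
    for key, ivs in by_key.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        by_key[key] = [tuple(iv) for iv in merged]
    return by_key


def scan_drach(
    genome: Mapping[str, str], annotation: Annotation, flank: int = 10
) -> list[M6ASite]:
    """Find every DRACH-centred adenosine in exonic sequence, both strands.

    The minus strand is scanned on the reverse complement and positions are
    reported on forward coordinates.  Each site carries a region of
    ``position ± flank`` (clipped at chromosome ends); counts are empty.
    Motifs must lie fully within a merged exonic interval.
    """
    sites: list[M6ASite] = []
    for (chrom, strand), intervals in sorted(
        _merged_exonic_intervals(annotation).items()
    ):
        chrom_seq = genome[chrom]
        chrom_len = len(chrom_seq)
        for start, end in intervals:
            seq = chrom_seq[start:end].upper()
            if strand == "-":
                seq = reverse_complement(seq)
            for i in range(len(seq) - 4):
                motif = seq[i : i + 5]
                if not is_drach(motif):
                    continue
                if strand == "+":
                    pos = start + i + 2
                else:
                    pos = end - 1 - (i + 2)
                region = (max(0, pos - flank), min(chrom_len, pos + flank + 1))
                sites.append(M6ASite(chrom, pos, strand, motif, region))
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


# ---------------------------------------------------------------------------
# filtering and differential testing
# ---------------------------------------------------------------------------

def filter_sites(
    sites: Iterable[M6ASite],
    min_coverage: int = 5,
    min_samples: int = 2,
) -> list[M6ASite]:
    """Keep sites with total >= min_coverage in >= min_samples samples and
    modified > 0 in >= min_samples samples (the two criteria are counted
    over samples independently)."""
    kept = []
    for s in sites:
        n_cov = sum(1 for _, tot in s.counts.values() if tot >= min_coverage)
        n_mod = sum(1 for mod, _ in s.counts.values() if mod > 0)
        if n_cov >= min_samples and n_mod >= min_samples:
            kept.append(s)
    return kept


def diff_m6a(
    sites: Iterable[M6ASite],
    conditions: Mapping[str, str],
    cond_a: str,
    cond_b: str,
    lfc: float = 0.5,
    alpha: float = 0.01,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Differential modification per site between two conditions.

    Counts are pooled within each condition; Fisher's exact test on
    [mod_A, unmod_A; mod_B, unmod_B]; log2FC on modification frequencies
    with pseudo-frequency ``eps``.  Sites with zero pooled total in either
    condition are flagged untestable.  Columns: site, chrom, position,
    strand, motif, freq_a, freq_b, log2fc, p_value, significant, testable.
    """
    rows = []
    for s in sites:
        mod = {cond_a: 0, cond_b: 0}
        tot = {cond_a: 0, cond_b: 0}
        for sample, (m, t) in s.counts.items():
            cond = conditions.get(sample)
            if cond in mod:
                mod[cond] += m
                tot[cond] += t
        testable = tot[cond_a] > 0 and tot[cond_b] > 0
        freq_a = mod[cond_a] / tot[cond_a] if tot[cond_a] else np.nan
        freq_b = mod[cond_b] / tot[cond_b] if tot[cond_b] else np.nan
        if testable:
            log2fc = float(np.log2((freq_b + eps) / (freq_a + eps)))
            p = fisher_exact_two_sided(
                np.array(
                    [
                        [mod[cond_a], tot[cond_a] - mod[cond_a]],
                        [mod[cond_b], tot[cond_b] - mod[cond_b]],
                    ]
                )
            )
        else:
            log2fc, p = np.nan, 1.0
        rows.append(
            {
                "site": s.key,
                "chrom": s.chrom,
                "position": s.position,
                "strand": s.strand,
                "motif": s.motif,
                "freq_a": freq_a,
                "freq_b": freq_b,
                "log2fc": log2fc,
                "p_value": p,
                "testable": testable,
                "significant": testable and abs(log2fc) > lfc and p < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site", "chrom", "position", "strand", "motif",
            "freq_a", "freq_b", "log2fc", "p_value", "testable", "significant",
        ],
    )


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

def metagene(
    sites: Iterable[M6ASite], annotation: Annotation
) -> tuple[list[MetagenePosition], dict[str, int]]:
    """Place each site on the rescaled transcript axis.

    Each site maps to every same-strand transcript with a CDS partition
    whose exons contain it; relative position = segment base (0/1/2) +
    within-segment offset / segment length.  Sites landing on no eligible
    transcript are counted in the returned skip tally.
    """
    by_key: dict[tuple[str, str], list] = {}
    for t in annotation:
        if t.cds:
            by_key.setdefault((t.chrom, t.strand), []).append(t)
    positions: list[MetagenePosition] = []
    skipped = {"no_transcript": 0, "no_cds": 0}
    for s in sites:
        txs = by_key.get((s.chrom, s.strand), [])
        placed = False
        for t in txs:
            tpos = t.genomic_to_transcript(s.position)
            if tpos is None:
                continue
            utr5, cds_len, utr3 = t.utr_cds_lengths()
            if tpos < utr5:
                segment, rel = "5UTR", tpos / utr5
            elif tpos < utr5 + cds_len:
                segment, rel = "CDS", 1.0 + (tpos - utr5) / cds_len
            else:
                if utr3 == 0:
                    continue
                segment, rel = "3UTR", 2.0 + (tpos - utr5 - cds_len) / utr3
            positions.append(
                MetagenePosition(s.key, t.transcript_id, segment, rel)
            )
            placed = True
        if not placed:
            skipped["no_transcript"] += 1
    return positions, skipped


def metagene_density(
    positions: Iterable[MetagenePosition], bins: int = 90
) -> tuple[np.ndarray, np.ndarray]:
    """Binned density of metagene positions over [0, 3], for plotting."""
    rel = np.array([p.relative for p in positions], dtype=float)
    return np.histogram(rel, bins=bins, range=(0.0, 3.0), density=False)
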