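"""Read-to-transcript quantification, CPM normalization, and Fisher's-exact
differential expression.

The differential framework follows the pooled-sample design of nanopore
direct-RNA studies without biological replicates within a pool: replicate
columns of a condition are summed, each feature is tested against the rest
of the library with a two-sided Fisher's exact test, and fold change is
computed on CPM with a 0.01 pseudocount.  Calls require both
|log2FC| > 0.5 (strict) and p < 0.01 (strict); Benjamini-Hochberg q-values
are reported alongside but do not gate the calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import Annotation, SplicedRead

logger = logging.getLogger(__name__)


@dataclass
class CountsMatrix:
    """Feature x sample integer counts with per-sample condition labels."""

    df: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.df.columns if c not in self.conditions]
        if self.conditions and missing:
            raise ValueError(f"samples without condition label: {missing}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.df.columns if self.conditions.get(s) == condition]

    def pooled(self, condition: str) -> pd.Series:
        cols = self.samples_of(condition)
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return self.df[cols].sum(axis=1)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(
    reads_by_sample: Mapping[str, Iterable[SplicedRead]],
    annotation: Annotation,
    min_mapq: int = 1,
    conditions: Mapping[str, str] | None = None,
) -> CountsMatrix:
    """Count reads per transcript and sample.

    A multi-exon read is assigned to the transcript whose intron chain
    equals the read's chain (ties to the smallest transcript id); a
    single-exon read goes to the single-exon transcript it best reciprocally
    overlaps on the same strand.  Reads with mapq < ``min_mapq`` are
    excluded; unassigned reads are counted and logged.
    """
    chain_index: dict[tuple, str] = {}
    single_index: dict[tuple[str, str], list[TupleTx]] = {}
    for t in annotation:
        if t.intron_chain:
            key = t.chain_key()
            if key not in chain_index or t.transcript_id < chain_index[key]:
                chain_index[key] = t.transcript_id
        else:
            single_index.setdefault((t.chrom, t.strand), []).append(
                (t.start, t.end, t.transcript_id)
            )
    for lst in single_index.values():
        lst.sort()

    samples = sorted(reads_by_sample)
    tids = sorted(annotation.transcripts)
    tally: dict[str, dict[str, int]] = {s: {} for s in samples}
    assignments: dict[str, str] = {}
    n_unassigned = 0
    n_lowmapq = 0
    for sample in samples:
        for read in reads_by_sample[sample]:
            if read.mapq < min_mapq:
                n_lowmapq += 1
                continue
            tid = _assign(read, chain_index, single_index)
            if tid is None:
                n_unassigned += 1
                continue
            tally[sample][tid] = tally[sample].get(tid, 0) + 1
            assignments[read.read_id] = tid
    counts = pd.DataFrame(
        {s: pd.Series(tally[s], dtype=int) for s in samples},
        index=tids,
    ).fillna(0).astype(int)
    if n_unassigned or n_lowmapq:
        logger.info(
            "quantify: %d reads below mapq %d, %d unassigned",
            n_lowmapq,
            min_mapq,
            n_unassigned,
        )
    cm = CountsMatrix(counts, dict(conditions) if conditions else {})
    cm.assignments = assignments  # read_id -> transcript_id, for tail analysis
    return cm


TupleTx = tuple[int, int, str]


def _assign(read: SplicedRead, chain_index, single_index) -> str | None:
    if read.junctions:
        return chain_index.get(read.chain_key())
    cands = single_index.get((read.chrom, read.strand), [])
    rb = read.blocks[0]
    best: tuple[float, str] | None = None
    for start, end, tid in cands:
        ov = min(end, rb[1]) - max(start, rb[0])
        if ov <= 0:
            continue
        frac = min(ov / (end - start), ov / (rb[1] - rb[0]))
        if best is None or (frac, tid) > best:
            best = (frac, tid)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# CPM and Fisher DE
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample (column) to sum to one million."""
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero column sum for samples {bad}")
    return counts / sums * 1e6


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (sum of hypergeometric
    probabilities <= the observed table's)."""
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_de(
    counts: CountsMatrix,
    cond_a: str,
    cond_b: str,
    pseudo: float = 0.01,
    lfc: float = 0.5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-feature Fisher's-exact differential expression between two
    conditions (replicates pooled by summation).

    For each feature the 2x2 table is [count_A, rest_A; count_B, rest_B].
    log2FC = log2((CPM_B + pseudo) / (CPM_A + pseudo)) on pooled CPM.
    ``significant`` requires |log2FC| > lfc and p < alpha, both strict.
    Output columns: cpm_a, cpm_b, log2fc, p_value, q_value, significant.
    """
    a = counts.pooled(cond_a)
    b = counts.pooled(cond_b)
    tot_a, tot_b = int(a.sum()), int(b.sum())
    cpm_a = a / tot_a * 1e6 if tot_a else a * 0.0
    cpm_b = b / tot_b * 1e6 if tot_b else b * 0.0
    log2fc = np.log2((cpm_b + pseudo) / (cpm_a + pseudo))
    pvals = np.ones(len(a))
    for i, (ca, cb) in enumerate(zip(a.to_numpy(), b.to_numpy())):
        if ca == 0 and cb == 0:
            continue
        pvals[i] = fisher_exact_two_sided(
            np.array([[ca, tot_a - ca], [cb, tot_b - cb]])
        )
    qvals = stats.false_discovery_control(pvals, method="bh")
    out = pd.DataFrame(
        {
            "cpm_a": cpm_a,
            "cpm_b": cpm_b,
            "log2fc": np.where((a == 0) & (b == 0), 0.0, log2fc),
            "p_value": pvals,
            "q_value": qvals,
        },
        index=a.index,
    )
    out["significant"] = (out["log2fc"].abs() > lfc) & (out["p_value"] < alpha)
    return out
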