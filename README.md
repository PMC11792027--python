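# isoformatlas

Nanopore direct RNA sequencing (DRS) reads full-length native transcripts,
which makes it possible to analyse four layers of RNA regulation that
short-read RNA-seq cannot resolve: isoform-level expression, alternative
splicing, poly(A) tail-length dynamics, and m6A modification. The catch is
that raw long reads are noisy — splice boundaries wobble by a few bases,
many reads are 5'-truncated, and alignment artifacts inflate deletions — so
the reads must be refined against orthogonal short-read and ATAC-seq
evidence before any of those layers can be trusted.

`isoformatlas` is a tested, reusable implementation of that integrative
workflow for bulk multi-condition designs (e.g. organs profiled under fed
vs. fasting states). It is aimed at bioinformaticians who want the analysis
logic of such studies as a library with explicit contracts, plus a
ground-truth simulator to validate every stage.

## What it computes

**Isoform refinement** (`isoform_refine`) — reads with total deletion
length > 100 nt are removed; reads whose strand-aware 5' end does not fall
inside an ATAC open-chromatin peak are removed (truncated starts); each
splice junction is snapped to the nearest short-read junction within ±15 bp
that is supported by ≥ 3 uniquely mapping short reads, rejecting reads with
unmatchable junctions; corrected reads are collapsed by exact intron chain
into transcript models (support ≥ 3 reads), grouped into genes by exonic
overlap.

**Classification** (`annotation_compare`) — each de-novo transcript gets a
GffCompare-style class code against a reference annotation: `=` exact
intron-chain match; `m j o x i y u` → "different"; `c k n e s p r` →
"others"; `u` (no exonic overlap with any reference transcript) flags a
novel gene. Also: tissue-specific transcripts (intron chain present in
exactly one tissue), per-gene dominant transcripts, and a longest-ORF
coding stand-in.

**Differential layers** — all four use the same pooled-sample Fisher's
exact machinery:

| layer | unit | 2×2 table | call |
|---|---|---|---|
| expression | transcript (mapq ≥ 1 reads) | feature vs. rest of library | \|log2FC\| > 0.5 and p < 0.01 |
| splicing | ES/IR/ALT5/ALT3/AF/AL/MX event | inclusion vs. exclusion counts | p < 0.01 |
| poly(A) | transcript (mapq ≥ 5 reads) | Mann-Whitney U on tail lengths | \|Δmedian\| > 10 nt and p < 0.05 |
| m6A | DRACH site (coverage ≥ 5 in ≥ 2 samples, modified in ≥ 2) | modified vs. unmodified counts | \|log2FC\| > 0.5 and p < 0.01 |

Fold changes are computed on CPM with a 0.01 pseudocount,
log2FC = log2((CPM_B + 0.01)/(CPM_A + 0.01)). m6A sites are every adenosine
at position 3 of a DRACH motif (D=A/G/T, R=A/G, H=A/C/T) in exonic
sequence, and each site is positioned on a metagene axis (5'UTR → [0,1),
CDS → [1,2), 3'UTR → [2,3]).

**Simulator** (`synthetic_data`) — a seeded generator producing a complete
miniature dataset (genome FASTA, annotation GTF with CDS, per-sample read
tables with junction jitter/truncation/deletions, junction table, ATAC
peaks, gamma-distributed tails, binomial m6A counts) with a recorded
`TruthSet`, plus an `evaluate` harness reporting precision/recall per
layer.

## Worked example

```bash
isoformatlas all --out-dir run --seed 1
```

runs simulate → refine → classify → diffexp → diffsplice → polya → m6a →
evaluate and prints `8 stages completed -> run`. The run directory then
contains per-stage tables; `run/metrics.tsv` holds the recovery of every
planted effect:

```
layer     n_true  n_called  tp   precision  recall
isoforms  135     135       135  1.0        1.0
de        14      15        14   0.933      1.0
as        8       10        8    0.8        1.0
polya     14      14        14   1.0        1.0
m6a       22      22        22   1.0        1.0
```

Reading: all 135 simulated intron chains were reconstructed exactly from
the noisy reads; all 14 planted 4-fold expression changes, all 8 planted
ΔPSI = 0.4 exon-skip switches, all 14 planted +20 nt tail shifts, and all
22 planted modification-fraction changes (0.1 → 0.4) were called, with a
handful of chance false positives at the configured thresholds (e.g. 2 of
~100 null splicing events at p < 0.01).

The same stages are available individually (`simulate`, `refine`,
`classify`, `tissue-specific`, `dominant`, `diffexp`, `diffsplice`,
`polya`, `m6a scan|diff|metagene`, `evaluate`), and everything is importable
as a library:

```python
from isoformatlas import SimConfig, simulate, refine, fisher_de
```

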