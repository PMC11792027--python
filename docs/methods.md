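# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `isoformatlas`. It states nothing the test suite
and `scripts/acceptance.py` do not themselves compute.

## Coordinate and data conventions

All in-memory coordinates are 0-based half-open on a named chromosome
strand. GTF (1-based closed, GENCODE attribute dialect) is converted at the
I/O boundary and nowhere else. A transcript is an ordered chain of disjoint
exons; its identity for isoform matching is the *intron chain* — the
ordered (donor, acceptor) pairs in genomic coordinates — deliberately
ignoring transcript start/end, which in collapsed long-read models are
data-dependent (median read ends). Unknown strand `.` is rejected for
transcripts and reads (strand is load-bearing for junction matching and
DRACH scanning) but allowed for peaks.

Long reads enter through a neutral tab-separated dialect (blocks, total
deletion, mapq, optional tail length) rather than BAM: the analysis needs
only block geometry and three alignment scalars, and plain text keeps the
whole pipeline testable at desk scale.

## Refinement model

The refinement assumes three noise processes on otherwise full-length
reads, each paired with an orthogonal evidence source:

1. **Alignment artifacts** — reads carrying > 100 nt of total deletion are
   removed (strictly greater; 100 is kept).
2. **5' truncation** — a read is kept only if its strand-aware 5' end lies
   inside an ATAC open-chromatin peak (point in half-open interval). This
   treats chromatin accessibility as a TSS oracle; it removes truncated
   reads but also genuine reads of promoters absent from the peak set.
3. **Splice-site wobble** — each read junction is snapped to a short-read
   junction whose donor and acceptor are both within ±15 bp and whose
   unique-read support is ≥ 3. The snap target minimizes
   max(|Δdonor|, |Δacceptor|); ties go to higher support, then smaller
   donor — a deterministic rule. Reads with any unmatchable junction, or
   whose re-derived blocks would be degenerate, are rejected and excluded
   from collapsing.

Filter order is deletion → TSS → correction → collapse. The filters are
idempotent and commute, so the order affects only the per-stage removal
counts in the log, not the final read set.

**Collapse.** Multi-exon reads group by exact corrected intron chain;
single-exon reads by single-linkage reciprocal overlap ≥ 0.5 on the same
strand. Transcript ends are the lower median of the largest single-linkage
end cluster (gap ≤ 100 bp); groups with < 3 reads are dropped; genes are
single-linkage components of exonic overlap per strand. The collapse knobs
(end window 100 bp, support 3) are stand-ins for tool defaults that vary
across versions; both are exposed in `CorrectionParams`. Transcript and
gene ids are UUID-formatted MD5 digests of the group geometry, so identical
inputs give identical ids without global state.

## Classification

The class-code scheme is a decision tree evaluated per (query, reference)
pair in priority order `=`, `c`, `k`, `j`, `e`, `i`, `o`, `x`, with `u`
when no pair relation exists on either strand. `=` requires identical
intron chains (single-exon pairs additionally need exonic overlap, since
two empty chains are vacuously equal). Best match among references is the
highest-priority code, then longest exonic overlap, then smallest reference
id. The fuzzy codes `m n s p r y` are accepted on input and mapped to
categories (they occur in GffCompare output) but never emitted: they encode
fuzzy/repeat/pre-mRNA cases this splice-exact comparison does not produce.
The category mapping is fixed: `=` matched; `m j o x i y u` different;
`c k n e s p r` others. The prose notion of "others" (partial matches)
overlaps semantically with "different"; the explicit code lists are
authoritative here.

Tissue-specific transcripts are keyed by (chrom, strand, intron chain)
only; single-exon transcripts therefore share a key per locus-strand, a
deliberate coarsening consistent with chain-based identity. The longest-ORF
utility is a coding-potential stand-in (ATG-initiated, in-frame stop
required, ties to the 5'-most start); it is not a learned coding/non-coding
classifier.

## Differential machinery

All count layers use the same statistic: a two-sided Fisher's exact test
("sum of tables with probability ≤ observed"), with replicate columns
pooled by summation first — the appropriate model for pooled-sample designs
with no within-condition biological replication, where the test's unit of
evidence is the read, not the sample.

* **Expression**: table [count, rest-of-library] per condition; CPM
  normalization to 1e6 per sample; log2FC on pooled CPM with pseudocount
  0.01; a call requires |log2FC| > 0.5 *and* p < 0.01, both strict.
  Benjamini–Hochberg q-values are reported but do not gate calls (the raw-p
  convention of the upstream workflow); at these thresholds the discrete
  test is conservative. The table construction (feature vs. rest) is the
  standard reading of per-feature Fisher differential expression.
* **Splicing**: events are enumerated from the annotation by pairwise
  isoform comparison within each gene, then quantified from full-length
  transcript assignments (the long-read advantage; no junction-spanning
  short reads). Seven types: ES, IR, ALT5/ALT3 (strand-aware), AF/AL
  (identical remaining chain and non-overlapping terminal exons), MX.
  A junction pair sharing one end qualifies as an alternative splice site
  only if an exon of the shorter-intron isoform spans the other boundary;
  otherwise the pair is an exon-skipping reflection and only the ES event
  is emitted — without this guard every exon skip would spawn two spurious
  ALT events. Inclusion/exclusion sets are recomputed over *all* gene
  isoforms matching the defining junction pattern, events deduplicate by
  (type, coordinates), and PSI = incl/(incl+excl) per condition. Multiple
  exons skipped between the same anchors form one event (one contiguous
  skipped block). Call: p < 0.01.
* **Poly(A)**: per-transcript tail-length samples (reads with mapq ≥ 5 and
  a tail estimate); shift = median_B − median_A; two-sided Mann–Whitney U
  (Kolmogorov–Smirnov switchable) — a rank test because tail-length
  distributions are right-skewed; the delta is defined on medians for the
  same reason. Call: |Δ| > 10 nt and p < 0.05, both strict. Pairs with
  < 10 tails in either condition are marked untestable (an added floor;
  the shift rule itself states none). Whether the upstream tooling used
  means or medians and which test it applied is not recorded; these are
  this package's choices, config-exposed.
* **m6A**: count-based site model — per-site per-sample (modified, total)
  reads are the input contract; signal-level inference from raw nanopore
  current is explicitly out of scope, so upstream of this package those
  counts must come from a signal caller, and here they come from the
  simulator. Candidate sites are DRACH-centred adenosines in exonic
  sequence (minus strand scanned on the reverse complement, positions
  reported on forward coordinates), each with a ±10 bp region. Filters:
  total ≥ 5 in ≥ 2 samples and modified > 0 in ≥ 2 samples, the two
  criteria counted over all samples independently ("modification present
  in a sample" is read as modified > 0, and recurrence is counted across
  all samples, not per condition — both underdetermined upstream).
  Differential: Fisher on pooled modified/unmodified; log2FC on
  modification frequencies with pseudo-frequency 0.01 (mirroring the
  expression pseudocount); call |log2FC| > 0.5 and p < 0.01. Metagene
  positions rescale the transcript axis so 5'UTR → [0,1), CDS → [1,2),
  3'UTR → [2,3], computed per same-strand CDS-bearing transcript
  containing the site.

## Synthetic study conditions

The generator emulates the data structure the analysis assumes, not
nanopore chemistry. Defaults define the desk-scale study: 50 genes on 3
chromosomes, 2–4 isoforms per gene built by skipping distinct internal
exons (so every splicing event is knowable in closed form), exons 120–300
bp, introns 150–400 bp, 2 conditions × 2 replicates, expected 35
reads/transcript/sample (~21k reads total — the full pipeline runs in
seconds), junction jitter ~ Normal(0, 5) truncated at ±15 (within the
correction window, so full chain recovery is attainable), 10% of reads 5'
truncated beyond the 100-bp TSS peaks, 8% of reads given > 100 nt
deletions, mapq 0/4/60 with probabilities 0.05/0.03/0.92, decoy junctions
at support ≤ 2.

Planted effects: 4-fold expression changes on 10% of transcripts, split
evenly between up- and down-regulation so condition library sizes stay
balanced (an unbalanced design would shift every null feature's CPM ratio
by the library-size ratio — a real composition effect this desk-scale
benchmark deliberately avoids); exon-skip PSI switches 0.7 → 0.3 in 16% of
genes (8 genes at the default size — enough planted events that a single
chance false positive cannot dominate the precision estimate); +20 nt tail
shifts on 10% of transcripts (tails gamma with shape 30, means 70–100 nt
across transcripts, echoing the tissue-level range such studies report);
modification-fraction changes 0.1 → 0.4 on 20% of the ~108 well-covered
DRACH sites (coverage ~ Poisson(50) per sample), with 10% of sites kept
below coverage to exercise the filter.

DE and splicing effects are planted in disjoint gene sets, and each
layer's evaluation universe excludes the other's genes: a planted
transcript-level fold change *is* a genuine isoform-ratio change and vice
versa, so without the exclusion true effects would be scored as false
positives of the neighbouring layer.

What the simulator does **not** model — and hence what passing tests do not
show about real data: base-level sequencing error and mapping ambiguity,
internal priming and genuine TSS heterogeneity, overdispersion beyond
Poisson/binomial counting noise, transcripts sharing exons across genes,
incomplete junction tables, and real DRACH-context modification
preferences. Recovery metrics here validate the analysis logic, not
end-to-end performance on tissue data.

## Numerical choices and degenerate inputs

* Transcript-end medians are lower medians (integer coordinates, no
  interpolation); the largest end cluster wins, ties to the leftmost.
* A feature absent in both conditions: p = 1, log2FC = 0. Zero pooled
  total on one side of a splicing/m6A/tail comparison: untestable, never
  significant.
* All significance gates are strict inequalities; boundary values
  (deletion 100, offset 15, support 3, mapq 1/5, |log2FC| = 0.5,
  Δ = 10 nt) behave exactly as stated, and the acceptance suite pins each
  boundary.
* Every stochastic step draws from one `numpy` generator seeded from the
  config; outputs are written in sorted order, so equal seeds give
  byte-identical files.

## Pipeline

`run_all` chains simulate → refine → classify → diffexp → diffsplice →
polya → m6a → evaluate over plain files in one run directory, with a JSON
manifest recording parameters, input hashes, per-stage record counts, and
any config overrides. Plain files plus a manifest were chosen over a
workflow engine: the whole run is seconds long, and file-level hashing is
what the determinism guarantee is stated against. Evaluation maps collapsed
transcript ids to truth ids by intron chain; splicing events compare by
coordinate-based event ids, m6A sites by genomic key.

## Known limitations

* Single-exon transcript handling is coarse: identity is reciprocal
  overlap, not ends, and the tissue-specific key collapses all single-exon
  transcripts per locus-strand.
* `e`-code semantics are simplified to "single-exon query overlapping a
  reference exon"; full GffCompare parity (including its fuzzy codes) is a
  non-goal.
* The splicing taxonomy unifies two upstream tools' event sets into one
  deduplicated enumeration; counts are not comparable tool-by-tool.
* Fisher on pooled counts treats reads as independent evidence; with true
  biological replicates a dispersion-modelling test would be preferred and
  is out of scope.
* The m6A layer starts from counts; no statement is made about how well
  any signal-level caller produces them.
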