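"""Seeded generator of a complete miniature direct-RNA study with recorded
ground truth for every downstream analysis layer.

The generator emulates the data structure the analysis assumes: multi-exon
genes with several isoforms (built by skipping internal exons, so splicing
events are known), condition-dependent transcript abundances, long reads
with splice-junction jitter and 5' truncation, a short-read junction table,
ATAC peaks at true TSSs, gamma-distributed poly(A) tails with planted
condition shifts, and binomial m6A counts at DRACH sites with planted
modification changes.  Everything derives from one ``numpy`` generator
seeded from ``SimConfig.seed``; the same seed yields byte-identical files.

Planted effects are assigned to disjoint gene sets per layer where layers
interact (a planted transcript-level fold change is also a genuine
isoform-ratio change, so DE genes are excluded from the splicing truth
universe and vice versa); details in the package methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .formats_io import (
    Annotation,
    GenomicInterval,
    JunctionTable,
    PeakSet,
    SplicedRead,
    TranscriptModel,
    read_gtf,
    write_fasta,
    write_gtf,
    write_junctions,
    write_peaks,
    write_reads,
)
from .m6a_sites import M6ASite, scan_drach

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset (defaults are the desk-scale
    study design; see docs/methods.md for the rationale of each value)."""

    n_genes: int = 50
    isoforms_per_gene: tuple[int, int] = (2, 4)
    exons_per_gene: tuple[int, int] = (5, 8)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (150, 400)
    intergenic_gap: tuple[int, int] = (800, 1500)
    n_chroms: int = 3
    n_tissues: int = 1
    conditions: tuple[str, str] = ("fed", "fasting")
    replicates: int = 2
    reads_per_transcript: float = 35.0
    junction_jitter_sd: float = 5.0
    max_jitter: int = 15
    tss_truncation_prob: float = 0.1
    deletion_mean: float = 20.0
    long_deletion_prob: float = 0.08
    long_deletion_range: tuple[int, int] = (101, 300)
    mapq_zero_prob: float = 0.05
    mapq_low_prob: float = 0.03
    peak_width: int = 100
    junction_support_range: tuple[int, int] = (5, 60)
    decoy_junction_prob: float = 0.1
    de_fraction: float = 0.1
    de_fold: float = 4.0
    as_fraction: float = 0.16
    as_psi: tuple[float, float] = (0.7, 0.3)
    tail_mean_range: tuple[float, float] = (70.0, 100.0)
    tail_shape: float = 30.0
    tail_shift_fraction: float = 0.1
    tail_shift: float = 20.0
    n_m6a_sites: int = 120
    m6a_coverage: float = 50.0
    m6a_base_fraction: float = 0.1
    m6a_diff_fraction: float = 0.2
    m6a_diff_high: float = 0.4
    m6a_lowcov_fraction: float = 0.1
    seed: int = 1

    def validate(self) -> None:
        for name in (
            "isoforms_per_gene", "exons_per_gene", "exon_length",
            "intron_length", "intergenic_gap", "junction_support_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        for name in (
            "tss_truncation_prob", "long_deletion_prob", "mapq_zero_prob",
            "mapq_low_prob", "de_fraction", "as_fraction",
            "tail_shift_fraction", "m6a_base_fraction", "m6a_diff_fraction",
            "m6a_diff_high", "m6a_lowcov_fraction", "decoy_junction_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.exon_length[0] <= 2 * self.max_jitter + 20:
            raise ValueError(
                "exon_length minimum must exceed 2*max_jitter + 20 so that "
                "junction jitter cannot collapse an exon"
            )
        if self.intron_length[0] <= 2 * self.max_jitter + 20:
            raise ValueError("intron_length minimum too small for the jitter bound")
        if self.tss_truncation_prob > 0 and (
            self.exon_length[0] - 20 <= self.peak_width // 2 + 10
        ):
            raise ValueError(
                "exon_length minimum too small for 5' truncation to escape "
                "the TSS peak"
            )
        if self.exons_per_gene[0] < 3:
            raise ValueError("need >= 3 exons per gene to skip internal exons")

    @property
    def samples(self) -> dict[str, str]:
        """sample id -> condition, in deterministic order."""
        return {
            f"{cond}_r{i + 1}": cond
            for cond in self.conditions
            for i in range(self.replicates)
        }


@dataclass
class TruthSet:
    """Ground truth recorded by :func:`simulate` for parameter recovery."""

    annotation: Annotation
    samples: dict[str, str]
    read_origin: dict[str, tuple[str, str]]  # read_id -> (transcript, sample)
    emissions: dict[str, dict[str, int]]  # transcript -> sample -> n reads
    de_true: dict[str, str]  # transcript -> up|down (direction in condition B)
    de_universe: list[str]
    de_genes: list[str]
    as_true: dict[str, float]  # event_id -> planted delta PSI
    as_genes: list[str]
    tail_true: dict[str, float]  # transcript -> planted shift (nt)
    tail_universe: list[str]
    m6a_true: list[str]  # site keys with planted change
    m6a_universe: list[str]

    def to_json(self, path) -> None:
        payload = {
            "samples": self.samples,
            "read_origin": {k: list(v) for k, v in self.read_origin.items()},
            "emissions": self.emissions,
            "de_true": self.de_true,
            "de_universe": self.de_universe,
            "de_genes": self.de_genes,
            "as_true": self.as_true,
            "as_genes": self.as_genes,
            "tail_true": self.tail_true,
            "tail_universe": self.tail_universe,
            "m6a_true": self.m6a_true,
            "m6a_universe": self.m6a_universe,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=0)

    @classmethod
    def load(cls, out_dir) -> "TruthSet":
        out_dir = Path(out_dir)
        with open(out_dir / "truth.json") as fh:
            d = json.load(fh)
        return cls(
            annotation=read_gtf(out_dir / "annotation.gtf"),
            samples=d["samples"],
            read_origin={k: tuple(v) for k, v in d["read_origin"].items()},
            emissions=d["emissions"],
            de_true=d["de_true"],
            de_universe=d["de_universe"],
            de_genes=d["de_genes"],
            as_true=d["as_true"],
            as_genes=d["as_genes"],
            tail_true=d["tail_true"],
            tail_universe=d["tail_universe"],
            m6a_true=d["m6a_true"],
            m6a_universe=d["m6a_universe"],
        )


# ---------------------------------------------------------------------------
# gene structure
# ---------------------------------------------------------------------------

def _build_genes(cfg: SimConfig, rng: np.random.Generator):
    """Lay out genes along chromosomes; return (transcripts, gene_meta,
    chrom_lengths).  gene_meta[gid] holds exons, strand, skipped-exon map."""
    cursors = {f"chr{i + 1}": 1000 for i in range(cfg.n_chroms)}
    txs: list[TranscriptModel] = []
    gene_meta: dict[str, dict] = {}
    for g in range(cfg.n_genes):
        chrom = f"chr{(g % cfg.n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        gap = int(rng.integers(*cfg.intergenic_gap))
        pos = cursors[chrom] + gap
        exons: list[tuple[int, int]] = []
        for k in range(n_exons):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        cursors[chrom] = pos
        gid = f"gene{g:03d}"
        # CDS span: interior of first exon .. interior of last exon
        cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) * 2 // 5
        cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) * 3 // 5
        n_iso = int(
            rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1)
        )
        n_iso = min(n_iso, n_exons - 1)  # one skip per extra isoform
        internal = list(range(1, n_exons - 1))
        skips = sorted(
            int(x) for x in rng.choice(internal, size=n_iso - 1, replace=False)
        )
        iso_exons = {f"{gid}.t0": list(exons)}
        skip_of = {}
        for k, skip_idx in enumerate(skips, start=1):
            tid = f"{gid}.t{k}"
            iso_exons[tid] = [e for i, e in enumerate(exons) if i != skip_idx]
            skip_of[tid] = skip_idx
        for tid, ex in iso_exons.items():
            cds = [
                (max(s, cds_start), min(e, cds_end))
                for s, e in ex
                if max(s, cds_start) < min(e, cds_end)
            ]
            txs.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(
                        GenomicInterval(chrom, s, e, strand) for s, e in ex
                    ),
                    cds=tuple(
                        GenomicInterval(chrom, s, e, strand) for s, e in cds
                    ),
                )
            )
        gene_meta[gid] = {
            "chrom": chrom,
            "strand": strand,
            "exons": exons,
            "skip_of": skip_of,
            "transcripts": sorted(iso_exons),
        }
    chrom_lengths = {c: cursors[c] + 1000 for c in cursors}
    return txs, gene_meta, chrom_lengths


def _es_event_id(meta: dict, skip_idx: int) -> str:
    """Canonical ES event id for skipping exon ``skip_idx`` of a gene."""
    exons = meta["exons"]
    d = exons[skip_idx - 1][1]
    a1 = exons[skip_idx][0]
    d2 = exons[skip_idx][1]
    a = exons[skip_idx + 1][0]
    return f"ES:{meta['chrom']}:{meta['strand']}:{d}-{a1}-{d2}-{a}"


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig, out_dir) -> tuple[dict[str, Path], TruthSet]:
    """Generate the full dataset under ``out_dir`` and return the file map
    plus the :class:`TruthSet` (also serialized as ``truth.json``)."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    txs, gene_meta, chrom_lengths = _build_genes(cfg, rng)
    annotation = Annotation.from_transcripts(txs)
    genome = {
        chrom: "".join(BASES[rng.integers(0, 4, size=length)])
        for chrom, length in sorted(chrom_lengths.items())
    }

    # ---- planted effects -------------------------------------------------
    gene_ids = sorted(gene_meta)
    multi_iso = [g for g in gene_ids if len(gene_meta[g]["transcripts"]) >= 2]
    perm = [multi_iso[i] for i in rng.permutation(len(multi_iso))]
    n_as = round(cfg.as_fraction * cfg.n_genes)
    as_genes = sorted(perm[:n_as])
    # AS genes are reduced to an inclusion/exclusion isoform pair so that the
    # planted PSI applies to exactly one exon-skipping event
    for g in as_genes:
        keep = gene_meta[g]["transcripts"][:2]
        gene_meta[g]["transcripts"] = keep
        for tid in list(annotation.transcripts):
            if tid.startswith(g + ".") and tid not in keep:
                del annotation.transcripts[tid]
    all_tids = sorted(annotation.transcripts)
    as_tids = {t for g in as_genes for t in gene_meta[g]["transcripts"]}

    de_pool = [t for t in all_tids if t not in as_tids]
    n_de = round(cfg.de_fraction * len(all_tids))
    de_pick = sorted(
        de_pool[i] for i in rng.choice(len(de_pool), size=n_de, replace=False)
    )
    de_true = {
        tid: ("up" if i % 2 == 0 else "down") for i, tid in enumerate(de_pick)
    }
    de_genes = sorted({annotation.transcripts[t].gene_id for t in de_pick})

    n_shift = round(cfg.tail_shift_fraction * len(all_tids))
    tail_pick = sorted(
        all_tids[i] for i in rng.choice(len(all_tids), size=n_shift, replace=False)
    )
    tail_true = {tid: cfg.tail_shift for tid in tail_pick}

    # per-transcript baselines
    base_rate: dict[str, float] = {}
    tail_mean: dict[str, float] = {}
    for tid in all_tids:
        base_rate[tid] = cfg.reads_per_transcript * float(rng.uniform(0.7, 1.3))
        tail_mean[tid] = float(rng.uniform(*cfg.tail_mean_range))
    # AS genes: pair shares a fixed gene total with condition-dependent PSI
    psi_a, psi_b = cfg.as_psi
    as_true: dict[str, float] = {}
    for g in as_genes:
        inc_tid, exc_tid = gene_meta[g]["transcripts"][0], gene_meta[g]["transcripts"][1]
        gene_total = 2.0 * cfg.reads_per_transcript
        base_rate[inc_tid] = gene_total  # scaled by psi at emission time
        base_rate[exc_tid] = gene_total
        skip_idx = gene_meta[g]["skip_of"][exc_tid]
        as_true[_es_event_id(gene_meta[g], skip_idx)] = psi_b - psi_a

    cond_b = cfg.conditions[1]

    def rate(tid: str, cond: str) -> float:
        gid = annotation.transcripts[tid].gene_id
        if gid in as_genes:
            inc_tid = gene_meta[gid]["transcripts"][0]
            psi = (psi_b if cond == cond_b else psi_a)
            share = psi if tid == inc_tid else 1.0 - psi
            return base_rate[tid] * share
        r = base_rate[tid]
        direction = de_true.get(tid)
        if direction == "up" and cond == cond_b:
            r *= cfg.de_fold
        elif direction == "down" and cond != cond_b:
            r *= cfg.de_fold
        return r

    # ---- reads -----------------------------------------------------------
    reads_by_sample: dict[str, list[SplicedRead]] = {}
    read_origin: dict[str, tuple[str, str]] = {}
    emissions: dict[str, dict[str, int]] = {t: {} for t in all_tids}
    counter = 0
    for sample, cond in cfg.samples.items():
        reads: list[SplicedRead] = []
        for tid in all_tids:
            t = annotation.transcripts[tid]
            n = int(rng.poisson(rate(tid, cond)))
            emissions[tid][sample] = n
            for _ in range(n):
                counter += 1
                rid = f"r{counter:06d}"
                read = _emit_read(rid, t, tid, cond, cfg, rng, tail_mean, tail_true)
                reads.append(read)
                read_origin[rid] = (tid, sample)
        reads_by_sample[sample] = reads

    # ---- junction table --------------------------------------------------
    junctions = JunctionTable()
    seen_j = set()
    for tid in all_tids:
        t = annotation.transcripts[tid]
        for d, a in t.intron_chain:
            key = (t.chrom, d, a, t.strand)
            if key not in seen_j:
                seen_j.add(key)
                junctions.add(
                    t.chrom, d, a, t.strand,
                    int(rng.integers(*cfg.junction_support_range)),
                )
    for gid in gene_ids:
        if rng.random() < cfg.decoy_junction_prob:
            meta = gene_meta[gid]
            exons = meta["exons"]
            k = int(rng.integers(0, len(exons) - 1))
            d, a = exons[k][1] + 50, exons[k + 1][0] + 50
            if (meta["chrom"], d, a, meta["strand"]) not in seen_j:
                junctions.add(meta["chrom"], d, a, meta["strand"], int(rng.integers(1, 3)))

    # ---- ATAC peaks at true TSSs ----------------------------------------
    peaks = PeakSet()
    half = cfg.peak_width // 2
    seen_p = set()
    for gid in gene_ids:
        meta = gene_meta[gid]
        first_tid = meta["transcripts"][0]
        t = annotation.transcripts[first_tid]
        tss = t.start if t.strand == "+" else t.end
        iv = (meta["chrom"], max(0, tss - half), tss + half)
        if iv not in seen_p:
            seen_p.add(iv)
            peaks.add(GenomicInterval(*iv, "."))

    # ---- m6A sites -------------------------------------------------------
    all_sites = scan_drach(genome, annotation, flank=10)
    n_pick = min(cfg.n_m6a_sites, len(all_sites))
    picked = sorted(
        (all_sites[i] for i in rng.choice(len(all_sites), size=n_pick, replace=False)),
        key=lambda s: (s.chrom, s.position, s.strand),
    )
    n_low = round(cfg.m6a_lowcov_fraction * n_pick)
    low_idx = set(
        int(i) for i in rng.choice(n_pick, size=n_low, replace=False)
    )
    usable = [i for i in range(n_pick) if i not in low_idx]
    n_diff = round(cfg.m6a_diff_fraction * len(usable))
    diff_idx = set(
        usable[int(i)] for i in rng.choice(len(usable), size=n_diff, replace=False)
    )
    m6a_true: list[str] = []
    m6a_universe: list[str] = []
    for i, site in enumerate(picked):
        lowcov = i in low_idx
        differential = i in diff_idx
        if not lowcov:
            m6a_universe.append(site.key)
        if differential:
            m6a_true.append(site.key)
        for sample, cond in cfg.samples.items():
            if lowcov:
                tot = int(rng.integers(1, 5))
            else:
                tot = max(5, int(rng.poisson(cfg.m6a_coverage)))
            frac = cfg.m6a_base_fraction
            if differential and cond == cond_b:
                frac = cfg.m6a_diff_high
            mod = int(rng.binomial(tot, frac))
            site.counts[sample] = (mod, tot)

    # ---- write everything -------------------------------------------------
    paths: dict[str, Path] = {}
    paths["genome"] = out_dir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["annotation"] = out_dir / "annotation.gtf"
    write_gtf(annotation, paths["annotation"])
    for sample in cfg.samples:
        p = out_dir / f"reads_{sample}.tsv"
        write_reads(reads_by_sample[sample], p)
        paths[f"reads_{sample}"] = p
    paths["junctions"] = out_dir / "junctions.tsv"
    write_junctions(junctions, paths["junctions"])
    paths["peaks"] = out_dir / "peaks.bed"
    write_peaks(peaks, paths["peaks"])
    paths["m6a_counts"] = out_dir / "m6a_counts.tsv"
    write_m6a_counts(picked, paths["m6a_counts"])
    if cfg.n_tissues > 1:
        # tissue annotations: random subsets sharing most transcripts
        for i in range(cfg.n_tissues):
            keep = [
                tid for tid in all_tids if rng.random() < 0.8
            ] or all_tids[:1]
            sub = Annotation.from_transcripts(
                annotation.transcripts[t] for t in keep
            )
            p = out_dir / f"annotation_tissue{i + 1}.gtf"
            write_gtf(sub, p)
            paths[f"annotation_tissue{i + 1}"] = p

    truth = TruthSet(
        annotation=annotation,
        samples=dict(cfg.samples),
        read_origin=read_origin,
        emissions=emissions,
        de_true=de_true,
        de_universe=sorted(t for t in all_tids if t not in as_tids),
        de_genes=de_genes,
        as_true=as_true,
        as_genes=as_genes,
        tail_true=tail_true,
        tail_universe=list(all_tids),
        m6a_true=sorted(m6a_true),
        m6a_universe=sorted(m6a_universe),
    )
    paths["truth"] = out_dir / "truth.json"
    truth.to_json(paths["truth"])
    return paths, truth


def _emit_read(
    rid: str,
    t: TranscriptModel,
    tid: str,
    cond: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    tail_mean: dict[str, float],
    tail_true: dict[str, float],
) -> SplicedRead:
    blocks = [[e.start, e.end] for e in t.exons]
    # junction jitter (truncated normal, clipped to the correction window)
    if cfg.junction_jitter_sd > 0:
        for k in range(len(blocks) - 1):
            dd = int(np.clip(round(rng.normal(0, cfg.junction_jitter_sd)),
                             -cfg.max_jitter, cfg.max_jitter))
            da = int(np.clip(round(rng.normal(0, cfg.junction_jitter_sd)),
                             -cfg.max_jitter, cfg.max_jitter))
            blocks[k][1] += dd
            blocks[k + 1][0] += da
    # 5' truncation beyond the TSS peak
    if rng.random() < cfg.tss_truncation_prob:
        lo = cfg.peak_width // 2 + 10
        if t.strand == "+":
            hi = blocks[0][1] - blocks[0][0] - 20
            if hi > lo:
                blocks[0][0] += int(rng.integers(lo, hi))
        else:
            hi = blocks[-1][1] - blocks[-1][0] - 20
            if hi > lo:
                blocks[-1][1] -= int(rng.integers(lo, hi))
    if rng.random() < cfg.long_deletion_prob:
        deletion = int(rng.integers(*cfg.long_deletion_range))
    else:
        deletion = min(int(rng.poisson(cfg.deletion_mean)), 100)
    u = rng.random()
    if u < cfg.mapq_zero_prob:
        mapq = 0
    elif u < cfg.mapq_zero_prob + cfg.mapq_low_prob:
        mapq = 4
    else:
        mapq = 60
    mean = tail_mean[tid]
    if tid in tail_true and cond == cfg.conditions[1]:
        mean += tail_true[tid]
    tail = float(rng.gamma(cfg.tail_shape, mean / cfg.tail_shape))
    return SplicedRead(
        read_id=rid,
        chrom=t.chrom,
        strand=t.strand,
        blocks=tuple((int(s), int(e)) for s, e in blocks),
        total_deletion=deletion,
        mapq=mapq,
        polya_length=tail,
    )


# ---------------------------------------------------------------------------
# m6A counts table I/O (long format)
# ---------------------------------------------------------------------------

def write_m6a_counts(sites: Iterable[M6ASite], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tposition\tstrand\tmotif\tsample\tmodified\ttotal\n")
        for s in sites:
            for sample in sorted(s.counts):
                mod, tot = s.counts[sample]
                fh.write(
                    f"{s.chrom}\t{s.position}\t{s.strand}\t{s.motif}\t"
                    f"{sample}\t{mod}\t{tot}\n"
                )


def read_m6a_counts(path, flank: int = 10) -> list[M6ASite]:
    sites: dict[tuple, M6ASite] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos_s, strand, motif, sample, mod_s, tot_s = (
                line.rstrip("\n").split("\t")
            )
            pos = int(pos_s)
            key = (chrom, pos, strand)
            if key not in sites:
                sites[key] = M6ASite(
                    chrom, pos, strand, motif,
                    (max(0, pos - flank), pos + flank + 1),
                )
            sites[key].counts[sample] = (int(mod_s), int(tot_s))
    return [sites[k] for k in sorted(sites)]


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

def _prf(true: set, called: set, universe: set | None = None) -> dict:
    if universe is not None:
        called = called & universe
        true = true & universe
    tp = len(true & called)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(true) if true else 1.0
    return {
        "n_true": len(true),
        "n_called": len(called),
        "tp": tp,
        "precision": precision,
        "recall": recall,
    }


def evaluate(truth: TruthSet, results: Mapping[str, object]) -> pd.DataFrame:
    """Precision/recall per analysis layer against the recorded truth.

    ``results`` may contain any of:

    * ``isoforms`` — an :class:`Annotation` or a set of chain keys;
    * ``de`` — transcript ids called differentially expressed;
    * ``as`` — significant splicing-event ids;
    * ``polya`` — transcript ids with a called tail shift;
    * ``m6a`` — site keys with a called modification change.

    Layer universes exclude features whose truth status is confounded by
    another planted layer (DE genes from the splicing universe and AS genes
    from the DE universe).
    """
    from .splice_events import enumerate_events

    rows = []
    if "isoforms" in results:
        called = results["isoforms"]
        if isinstance(called, Annotation):
            called = called.chain_keys()
        rows.append(
            {"layer": "isoforms", **_prf(truth.annotation.chain_keys(), set(called))}
        )
    if "de" in results:
        rows.append(
            {
                "layer": "de",
                **_prf(
                    set(truth.de_true),
                    set(results["de"]),
                    set(truth.de_universe),
                ),
            }
        )
    if "as" in results:
        de_genes = set(truth.de_genes)
        universe = {
            ev.event_id
            for ev in enumerate_events(truth.annotation)
            if ev.gene_id not in de_genes
        }
        rows.append(
            {
                "layer": "as",
                **_prf(set(truth.as_true), set(results["as"]), universe),
            }
        )
    if "polya" in results:
        rows.append(
            {
                "layer": "polya",
                **_prf(
                    set(truth.tail_true),
                    set(results["polya"]),
                    set(truth.tail_universe),
                ),
            }
        )
    if "m6a" in results:
        rows.append(
            {
                "layer": "m6a",
                **_prf(
                    set(truth.m6a_true),
                    set(results["m6a"]),
                    set(truth.m6a_universe),
                ),
            }
        )
    if not rows:
        raise ValueError("no recognized result layers to evaluate")
    return pd.DataFrame(
        rows, columns=["layer", "n_true", "n_called", "tp", "precision", "recall"]
    )
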