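"""End-to-end pipeline driver: simulate -> refine -> classify -> diffexp ->
diffsplice -> polya -> m6a -> evaluate.

Plain files plus a JSON run manifest instead of a workflow engine: every
stage reads from and writes into one run directory, no stage mutates its
inputs, and the manifest records parameters, input hashes, and per-stage
record counts.  Default thresholds are the study's quoted values and any
override is recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotation_compare, isoform_refine, m6a_sites, polya_dynamics
from . import quant_diff, splice_events, synthetic_data
from .formats_io import read_junctions, read_peaks, read_reads, write_gtf
from .isoform_refine import CorrectionParams
from .synthetic_data import SimConfig

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "refine",
    "classify",
    "diffexp",
    "diffsplice",
    "polya",
    "m6a",
    "evaluate",
)


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the quoted study values."""

    sim: SimConfig = field(default_factory=SimConfig)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    pseudo: float = 0.01
    lfc: float = 0.5
    alpha: float = 0.01
    quant_min_mapq: int = 1
    tail_min_mapq: int = 5
    tail_min_delta: float = 10.0
    tail_alpha: float = 0.05
    tail_min_reads: int = 10
    tail_test: str = "mannwhitney"
    m6a_min_coverage: int = 5
    m6a_min_samples: int = 2
    m6a_lfc: float = 0.5
    m6a_alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        overrides = []
        for key, value in raw.items():
            if key == "sim":
                for k, v in value.items():
                    if isinstance(v, list):
                        v = tuple(v)
                    setattr(cfg.sim, k, v)
                    overrides.append(f"sim.{k}={v}")
            elif key == "correction":
                for k, v in value.items():
                    setattr(cfg.correction, k, v)
                    overrides.append(f"correction.{k}={v}")
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
                overrides.append(f"{key}={value}")
            else:
                raise KeyError(f"unknown config key {key!r}")
        cfg.overrides = overrides
        for ov in overrides:
            logger.info("config override: %s", ov)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Run every stage in dependency order; returns the manifest dict
    (also written as ``manifest.json`` in the run directory)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.sim.seed = seed
    manifest: dict = {
        "parameters": {
            "sim": asdict(config.sim),
            "correction": asdict(config.correction),
            **{
                f.name: getattr(config, f.name)
                for f in dataclasses.fields(config)
                if f.name not in ("sim", "correction")
            },
        },
        "overrides": getattr(config, "overrides", []),
        "stages": [],
    }

    def record(name: str, n_records: int, **extra) -> None:
        manifest["stages"].append({"stage": name, "n_records": n_records, **extra})

    # 1. simulate ----------------------------------------------------------
    sim_dir = out_dir / "sim"
    paths, truth = synthetic_data.simulate(config.sim, sim_dir)
    record(
        "simulate",
        len(truth.read_origin),
        inputs={k: _sha256(p) for k, p in sorted(paths.items())},
    )

    # 2. refine ------------------------------------------------------------
    junctions = read_junctions(paths["junctions"])
    peaks = read_peaks(paths["peaks"])
    usable_by_sample: dict[str, list] = {}
    removed = {"deletion": 0, "tss": 0, "correction": 0}
    all_usable = []
    for sample in sorted(truth.samples):
        reads = read_reads(paths[f"reads_{sample}"])
        n0 = len(reads)
        reads = isoform_refine.filter_by_deletion(reads, config.correction)
        removed["deletion"] += n0 - len(reads)
        n1 = len(reads)
        reads = isoform_refine.filter_by_tss(reads, peaks)
        removed["tss"] += n1 - len(reads)
        corrected = isoform_refine.correct_reads(reads, junctions, config.correction)
        usable = [c for c in corrected if c.status != "rejected"]
        removed["correction"] += len(corrected) - len(usable)
        usable_by_sample[sample] = usable
        all_usable.extend(usable)
    collapsed, support = isoform_refine.collapse_reads(
        all_usable, config.correction
    )
    write_gtf(collapsed, out_dir / "collapsed.gtf")
    with open(out_dir / "support.tsv", "w") as fh:
        fh.write("#transcript_id\tn_reads\n")
        for tid in sorted(support):
            fh.write(f"{tid}\t{support[tid]}\n")
    record("refine", len(collapsed), removed=removed)

    # 3. classify ----------------------------------------------------------
    assignments_cls = annotation_compare.assign_class_codes(
        collapsed, truth.annotation
    )
    annotation_compare.assignments_frame(assignments_cls).to_csv(
        out_dir / "classification.tsv", sep="\t", index=False
    )
    record(
        "classify",
        len(assignments_cls),
        novel_genes=sum(a.novel_gene for a in assignments_cls),
    )

    # 4. diffexp -----------------------------------------------------------
    corrected_reads_by_sample = {
        s: [c.to_read() for c in lst] for s, lst in usable_by_sample.items()
    }
    counts = quant_diff.quantify(
        corrected_reads_by_sample,
        collapsed,
        min_mapq=config.quant_min_mapq,
        conditions=truth.samples,
    )
    cond_a, cond_b = config.sim.conditions
    de = quant_diff.fisher_de(
        counts, cond_a, cond_b,
        pseudo=config.pseudo, lfc=config.lfc, alpha=config.alpha,
    )
    de.to_csv(out_dir / "diffexp.tsv", sep="\t", index_label="transcript_id")
    record("diffexp", len(de), significant=int(de["significant"].sum()))

    # 5. diffsplice ---------------------------------------------------------
    events = splice_events.enumerate_events(collapsed)
    as_res = splice_events.test_events(
        events, counts, cond_a, cond_b, alpha=config.alpha
    )
    as_res.to_csv(out_dir / "diffsplice.tsv", sep="\t", index=False)
    record("diffsplice", len(as_res), significant=int(as_res["significant"].sum()))

    # 6. polya --------------------------------------------------------------
    reads_by_condition: dict[str, list] = {}
    for sample, lst in corrected_reads_by_sample.items():
        reads_by_condition.setdefault(truth.samples[sample], []).extend(lst)
    tails = polya_dynamics.collect_tails(
        reads_by_condition, counts.assignments, min_mapq=config.tail_min_mapq
    )
    shifts = polya_dynamics.test_shifts(
        tails, cond_a, cond_b,
        min_delta=config.tail_min_delta,
        alpha=config.tail_alpha,
        min_reads=config.tail_min_reads,
        method=config.tail_test,
    )
    shifts.to_csv(out_dir / "polya.tsv", sep="\t", index=False)
    record("polya", len(shifts), significant=int(shifts["significant"].sum()))

    # 7. m6a ----------------------------------------------------------------
    sites = synthetic_data.read_m6a_counts(paths["m6a_counts"])
    kept = m6a_sites.filter_sites(
        sites, config.m6a_min_coverage, config.m6a_min_samples
    )
    m6a_res = m6a_sites.diff_m6a(
        kept, truth.samples, cond_a, cond_b,
        lfc=config.m6a_lfc, alpha=config.m6a_alpha,
    )
    m6a_res.to_csv(out_dir / "m6a_diff.tsv", sep="\t", index=False)
    positions, _ = m6a_sites.metagene(kept, truth.annotation)
    with open(out_dir / "metagene.tsv", "w") as fh:
        fh.write("#site\ttranscript_id\tsegment\trelative\n")
        for p in positions:
            fh.write(f"{p.site_key}\t{p.transcript_id}\t{p.segment}\t{p.relative:.6f}\n")
    record("m6a", len(m6a_res), significant=int(m6a_res["significant"].sum()))

    # 8. evaluate ------------------------------------------------------------
    chain_to_truth = {
        t.chain_key(): t.transcript_id for t in truth.annotation
    }

    def to_truth_ids(ids) -> set[str]:
        out = set()
        for tid in ids:
            t = collapsed.transcripts.get(tid)
            if t is None:
                continue
            mapped = chain_to_truth.get(t.chain_key())
            out.add(mapped if mapped is not None else tid)
        return out

    results = {
        "isoforms": collapsed,
        "de": to_truth_ids(de.index[de["significant"]]),
        "as": set(as_res.loc[as_res["significant"], "event_id"]),
        "polya": to_truth_ids(
            shifts.loc[shifts["significant"], "transcript_id"]
        ),
        "m6a": set(m6a_res.loc[m6a_res["significant"], "site"]),
    }
    metrics = synthetic_data.evaluate(truth, results)
    metrics.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    record("evaluate", len(metrics))

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
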