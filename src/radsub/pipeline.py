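"""Stage orchestration: simulate -> preprocess -> catalog -> subtract ->
genotype -> reversals, with plain-text intermediates and resumability.

Each stage reads only the previous stage's files and skips itself when its
outputs already exist (delete a stage directory, or the final report, to
recompute from that point). Every TSV output carries the config hash and
seed in a ``#`` comment header; FASTA/FASTQ provenance lives in the run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .catalog import population_table, stack_tags, summarize_run
from .errors import ConfigurationError
from .markers import call_genetic_sex, detect_reversals, genotype_panel, markers_to_primers
from .preprocess import MidTable, clean_reads, demultiplex, quality_summary
from .simulate import SimConfig, default_individuals, simulate_population
from .subtract import cross_sex_screen, final_markers, genome_filter, select_candidates

log = logging.getLogger("radsub")


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed."""

    seed: int = 7
    sim: SimConfig = field(default_factory=SimConfig)
    tag_length: int = 110
    max_n_fraction: float = 0.10
    keep_residual: bool = True
    canonicalize: bool = True
    genome_size: float = 5.0e10
    min_depth: int = 1
    min_source_individuals: int | None = None  # None -> all source individuals
    seed_length: int = 20
    max_mismatch_fraction: float = 0.10
    n_select: int = 100
    source_sex: str = "female"
    primer_length: int = 20
    size_tolerance_bp: int = 5

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        seed = int(raw.pop("seed", 7))
        sim_raw = dict(raw.pop("sim", {}))
        sim_raw.setdefault("rng_seed", seed)
        known = {f for f in cls.__dataclass_fields__ if f not in ("sim",)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(seed=seed, sim=SimConfig(**sim_raw), **{k: raw[k] for k in raw})

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> list[str]:
        return [f"radsub pipeline", f"config_sha256={self.config_hash()}",
                f"seed={self.seed}"]


def _done(*paths: Path) -> bool:
    return all(p.exists() for p in paths)


def stage_simulate(cfg: PipelineConfig, out: Path) -> Path:
    """Write genomes, truth table, MID table and pooled paired FASTQ."""
    d = out / "sim"
    outputs = [d / n for n in ("male.fa", "female.fa", "truth.tsv", "mids.tsv",
                               "reads_R1.fastq", "reads_R2.fastq", "manifest.json")]
    if _done(*outputs):
        log.info("sim: outputs exist, skipping")
        return d
    d.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    pop = simulate_population(cfg.sim)
    rio.write_fasta([("male", pop.genomes.male_genome)], d / "male.fa")
    rio.write_fasta([("female", pop.genomes.female_genome)], d / "female.fa")
    truth = pd.DataFrame([
        {"region_id": w.region_id, "insertion_point": w.insertion_point,
         "length": len(w.sequence), "cassette_fragment": w.cassette_fragment}
        for w in pop.genomes.truth])
    rio.write_tsv(truth, d / "truth.tsv", header=cfg.provenance())
    rio.write_mid_table(
        MidTable(tuple((i.individual_id, i.sex, i.mid) for i in pop.individuals)),
        d / "mids.tsv", header=cfg.provenance())
    rio.write_paired_fastq(pop.reads, d / "reads_R1.fastq", d / "reads_R2.fastq")
    (d / "manifest.json").write_text(json.dumps({
        "config_sha256": cfg.config_hash(), "seed": cfg.seed,
        "emitted_counts": pop.emitted_counts,
        "n_fragments": {"male": len(pop.male_fragments),
                        "female": len(pop.female_fragments)},
    }, indent=2, sort_keys=True))
    log.info("sim: %d read pairs in %.1fs", len(pop.reads), time.perf_counter() - t0)
    return d


def stage_preprocess(cfg: PipelineConfig, out: Path) -> Path:
    """Demultiplex by MID, clean, write per-individual FASTQ + summary."""
    d = out / "preprocess"
    sim = out / "sim"
    if not (sim / "mids.tsv").exists():
        raise ConfigurationError(
            f"preprocess: MID table not found at {sim / 'mids.tsv'} — run simulate first")
    mids = rio.read_mid_table(sim / "mids.tsv")
    summary_path = d / "preprocess_summary.tsv"
    cleaned_paths = {i: d / f"{i}.cleaned.fastq" for i, _, _ in mids.rows}
    if _done(summary_path, *cleaned_paths.values()):
        log.info("preprocess: outputs exist, skipping")
        return d
    d.mkdir(parents=True, exist_ok=True)
    reads = rio.read_fastq(sim / "reads_R1.fastq")  # read-1 only, by design
    assigned, unassigned = demultiplex(reads, mids)
    rows = []
    for ind_id, stream in assigned.items():
        qs = quality_summary(stream) if stream else None
        cleaned = clean_reads(stream, tag_length=cfg.tag_length,
                              max_n_fraction=cfg.max_n_fraction,
                              keep_residual=cfg.keep_residual)
        rio.write_fastq(cleaned, cleaned_paths[ind_id])
        rows.append({
            "individual_id": ind_id, "sex": mids.sex_of[ind_id],
            "assigned_reads": len(stream),
            "assigned_bases": qs.base_count if qs else 0,
            "q20_pct": qs.q20_pct if qs else 0.0,
            "q30_pct": qs.q30_pct if qs else 0.0,
            "cleaned_reads": len(cleaned),
        })
    rows.append({"individual_id": "unassigned", "sex": "", "assigned_reads":
                 len(unassigned), "assigned_bases": 0, "q20_pct": 0.0,
                 "q30_pct": 0.0, "cleaned_reads": 0})
    rio.write_tsv(pd.DataFrame(rows), summary_path, header=cfg.provenance())
    log.info("preprocess: %d assigned streams, %d unassigned reads",
             len(assigned), len(unassigned))
    return d


def stage_catalog(cfg: PipelineConfig, out: Path) -> Path:
    """Stack cleaned reads into per-individual catalogs + run summary."""
    d = out / "catalog"
    mids = rio.read_mid_table(out / "sim" / "mids.tsv")
    pre = out / "preprocess"
    summary_path = d / "run_summary.tsv"
    cat_paths = {i: d / f"{i}.tags.tsv.gz" for i, _, _ in mids.rows}
    if _done(summary_path, *cat_paths.values()):
        log.info("catalog: outputs exist, skipping")
        return d
    d.mkdir(parents=True, exist_ok=True)
    pre_summary = rio.read_tsv(pre / "preprocess_summary.tsv")
    summaries = []
    for ind_id, sex, _ in mids.rows:
        reads = rio.read_fastq(pre / f"{ind_id}.cleaned.fastq")
        cat = stack_tags(reads, individual_id=ind_id, canonicalize=cfg.canonicalize)
        rio.write_tag_catalog(cat.counts, cat_paths[ind_id])
        row = pre_summary[pre_summary.individual_id == ind_id].iloc[0]
        summaries.append(summarize_run(
            cat, int(row.assigned_reads), int(row.assigned_bases),
            genome_size=cfg.genome_size, individual_id=ind_id, sex=sex))
    rio.write_tsv(population_table(summaries), summary_path, header=cfg.provenance())
    log.info("catalog: %d catalogs", len(summaries))
    return d


def stage_subtract(cfg: PipelineConfig, out: Path) -> Path:
    """Cross-sex screen + genome filter + random candidate selection."""
    d = out / "subtract"
    outputs = [d / "candidates.tsv", d / "markers.fasta", d / "selected.fasta"]
    if _done(*outputs):
        log.info("subtract: outputs exist, skipping")
        return d
    d.mkdir(parents=True, exist_ok=True)
    mids = rio.read_mid_table(out / "sim" / "mids.tsv")
    cats = {i: rio.read_tag_catalog(out / "catalog" / f"{i}.tags.tsv.gz")
            for i, _, _ in mids.rows}
    from .catalog import TagCatalog
    source_ids = [i for i, s, _ in mids.rows if s == cfg.source_sex]
    opposite_ids = [i for i, s, _ in mids.rows if s != cfg.source_sex]
    source = {i: TagCatalog(i, cats[i], sum(cats[i].values())) for i in source_ids}
    opposite = {i: set(cats[i]) for i in opposite_ids}
    candidates = cross_sex_screen(
        source, opposite, source_sex=cfg.source_sex,
        min_source_individuals=cfg.min_source_individuals,
        min_depth=cfg.min_depth, canonicalize=cfg.canonicalize)
    opposite_sex = "male" if cfg.source_sex == "female" else "female"
    genome = rio.read_fasta(out / "sim" / f"{opposite_sex}.fa")[opposite_sex]
    candidates = genome_filter(candidates, genome,
                               max_mismatch_fraction=cfg.max_mismatch_fraction,
                               seed_length=cfg.seed_length)
    markers = final_markers(candidates)
    selected = select_candidates(markers, cfg.n_select, cfg.seed) if markers else []
    log.info("subtract: %d unmatched, %d unmapped markers, %d selected (seed=%d)",
             len(candidates), len(markers), len(selected), cfg.seed)
    rio.write_tsv(pd.DataFrame([asdict(c) for c in candidates]),
                  d / "candidates.tsv", header=cfg.provenance())
    rio.write_fasta([(m.marker_id, m.sequence) for m in markers], d / "markers.fasta")
    rio.write_fasta([(m.marker_id, m.sequence) for m in selected], d / "selected.fasta")
    return d


def stage_genotype(cfg: PipelineConfig, out: Path) -> Path:
    """Derive primers from the discovered markers and genotype everyone."""
    d = out / "genotype"
    outputs = [d / "genotypes.tsv", d / "genetic_sex.tsv"]
    if _done(*outputs):
        log.info("genotype: outputs exist, skipping")
        return d
    d.mkdir(parents=True, exist_ok=True)
    mids = rio.read_mid_table(out / "sim" / "mids.tsv")
    selected = rio.read_fasta(out / "subtract" / "selected.fasta")
    from .subtract import CandidateMarker
    markers = [CandidateMarker(mid_, seq, cfg.source_sex, 0, "unmatched", "unmapped")
               for mid_, seq in selected.items()]
    templates = {i: list(rio.read_tag_catalog(out / "catalog" / f"{i}.tags.tsv.gz"))
                 for i, _, _ in mids.rows}
    panel = markers_to_primers(markers, primer_length=cfg.primer_length)
    geno = genotype_panel(templates, panel, size_tolerance_bp=cfg.size_tolerance_bp,
                          max_product_bp=cfg.tag_length + cfg.size_tolerance_bp)
    system = "ZW_female_marker" if cfg.source_sex == "female" else "XY_male_marker"
    calls = call_genetic_sex(geno, system=system)
    rio.write_tsv(geno.matrix.reset_index(), d / "genotypes.tsv",
                  header=cfg.provenance())
    rio.write_tsv(pd.DataFrame(
        [{"individual_id": i, "genetic_sex": s} for i, s in calls.items()]),
        d / "genetic_sex.tsv", header=cfg.provenance())
    log.info("genotype: %d markers x %d individuals", len(panel), len(templates))
    return d


def stage_report(cfg: PipelineConfig, out: Path) -> Path:
    """Headline tallies + reversal check against the simulated truth."""
    report_path = out / "report.tsv"
    if report_path.exists():
        log.info("report exists, skipping")
        return report_path
    mids = rio.read_mid_table(out / "sim" / "mids.tsv")
    candidates = rio.read_tsv(out / "subtract" / "candidates.tsv")
    markers = rio.read_fasta(out / "subtract" / "markers.fasta")
    selected = rio.read_fasta(out / "subtract" / "selected.fasta")
    calls_df = rio.read_tsv(out / "genotype" / "genetic_sex.tsv")
    calls = dict(zip(calls_df.individual_id, calls_df.genetic_sex))
    phenotype = mids.sex_of  # simulated phenotype == genetic truth
    report = detect_reversals(calls, phenotype)
    concordant = sum(1 for i in calls if calls[i] == phenotype[i])
    run_summary = rio.read_tsv(out / "catalog" / "run_summary.tsv")
    per_ind = run_summary[run_summary.sex.isin(["female", "male"])
                          & ~run_summary.individual_id.isin(
                              ["Subtotal", "Subaverage", "Total", "Average"])]
    rows = [
        {"quantity": "individuals", "value": len(mids.rows)},
        {"quantity": "distinct_tags_total", "value": int(per_ind.distinct_tags.sum())},
        {"quantity": "unmatched_candidates", "value": len(candidates)},
        {"quantity": "markers_unmapped", "value": len(markers)},
        {"quantity": "markers_selected", "value": len(selected)},
        {"quantity": "genotype_concordance_pct",
         "value": round(100.0 * concordant / len(calls), 2) if calls else 0.0},
        {"quantity": "reversals_female_to_male", "value": report.n_female_to_male},
        {"quantity": "reversals_male_to_female", "value": report.n_male_to_female},
    ]
    report_df = pd.DataFrame(rows, dtype=object)  # keep int tallies unpromoted
    rio.write_tsv(report_df, report_path, header=cfg.provenance())
    log.info("report: %d markers, %.1f%% concordance", len(markers),
             rows[5]["value"])
    return report_path


STAGES = ("simulate", "preprocess", "catalog", "subtract", "genotype", "report")


def run_pipeline(cfg: PipelineConfig, out: str | Path) -> Path:
    """Run every stage in order under *out*; returns the report path."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg, out)
    stage_preprocess(cfg, out)
    stage_catalog(cfg, out)
    stage_subtract(cfg, out)
    stage_genotype(cfg, out)
    return stage_report(cfg, out)
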