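"""End-to-end orchestration: simulate -> call -> annotate -> compare ->
summarize -> enrich, with a machine-readable run manifest.

Re-running with the same configuration produces byte-identical outputs;
logging goes to stderr, results only to files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import pandas as pd

from . import __version__
from .dtypes import GenomeSequence
from .enrichment import enrichment_frame, fisher_enrichment
from .group_compare import (
    affected_genes,
    compare_pools,
    summarize_categories,
)
from .io_formats import read_pileup, write_fasta, write_gff3, write_vcf
from .pooled_caller import CallerConfig, call_pool
from .synthetic_data import (
    SimulationConfig,
    TruthSet,
    mutagenize_pool,
    simulate_pileup,
    write_pileup,
)
from .variant_annotator import annotate_set, write_annotated_tsv
from .synthetic_data import generate_genome

logger = logging.getLogger(__name__)

POOL_LOW = "L"
POOL_HIGH = "H"


@dataclass
class PipelineConfig:
    """Merged configuration of every stage, with one global seed."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    window_bp: int = 300
    enrich_cutoff: float = 0.01
    enrich_cutoff_on: str = "fdr"
    min_identity: float = 50.0
    min_coverage_aln: float = 0.70
    max_evalue: float = 1e-5
    density_bin_bp: int = 400_000

    @property
    def seed(self) -> int:
        return self.sim.seed

    @classmethod
    def from_mapping(cls, mapping: Dict) -> "PipelineConfig":
        """Build from a flat or nested key->value mapping (YAML/INI style)."""
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        caller_fields = {f.name for f in dataclasses.fields(CallerConfig)}
        own_fields = {
            f.name for f in dataclasses.fields(cls) if f.name not in ("sim", "caller")
        }
        sim_kw = dict(mapping.get("sim", {}))
        caller_kw = dict(mapping.get("caller", {}))
        own_kw = {}
        for key, value in mapping.items():
            if key in ("sim", "caller"):
                continue
            if key in sim_fields:
                sim_kw[key] = value
            elif key in caller_fields:
                caller_kw[key] = value
            elif key in own_fields:
                own_kw[key] = value
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        for tup_key in ("gene_length_range", "indel_length_range"):
            if tup_key in sim_kw and not isinstance(sim_kw[tup_key], tuple):
                sim_kw[tup_key] = tuple(sim_kw[tup_key])
        return cls(
            sim=SimulationConfig(**sim_kw),
            caller=CallerConfig(**caller_kw),
            **own_kw,
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def manifest(self) -> Dict:
        """Every threshold the analysis applies, plus seed and version."""
        return {
            "poolvar_version": __version__,
            "seed": self.seed,
            "thresholds": {
                "min_coverage": self.caller.min_coverage,
                "min_var_freq": self.caller.min_var_freq,
                "strand_filter": self.caller.strand_filter,
                "min_baseq": self.caller.min_baseq,
                "min_mapq": self.caller.min_mapq,
                "p_threshold": self.caller.p_threshold,
                "min_strand_fraction": self.caller.min_strand_fraction,
                "window_bp": self.window_bp,
                "enrich_cutoff": self.enrich_cutoff,
                "enrich_cutoff_on": self.enrich_cutoff_on,
                "pangenome_min_identity_pct": self.min_identity,
                "pangenome_min_coverage": self.min_coverage_aln,
                "pangenome_max_evalue": self.max_evalue,
                "density_bin_bp": self.density_bin_bp,
            },
            "simulation": dataclasses.asdict(self.sim),
        }


@dataclass
class PipelineResult:
    """In-memory handles to everything the run produced."""

    genome: GenomeSequence
    models: list
    truth: Dict[str, TruthSet]
    calls: Dict[str, list]
    annotated_specific: Dict[str, list]
    comparison: object
    summary: object
    enrichment: list
    paths: Dict[str, Path]


def recovery_metrics(calls, truth: TruthSet) -> pd.DataFrame:
    """Sensitivity per carrier count k, plus overall precision.

    Returns one row per k with columns n_truth, n_recovered, sensitivity;
    the DataFrame carries overall precision in ``df.attrs['precision']``.
    """
    called_keys = {c.key for c in calls}
    truth_keys = truth.keys()
    rows = {}
    for rec in truth.records:
        n, r = rows.get(rec.k, (0, 0))
        rows[rec.k] = (n + 1, r + (1 if rec.key in called_keys else 0))
    df = pd.DataFrame(
        [(k, n, r, r / n) for k, (n, r) in sorted(rows.items())],
        columns=["k", "n_truth", "n_recovered", "sensitivity"],
    )
    df.attrs["precision"] = (
        sum(1 for key in called_keys if key in truth_keys) / len(called_keys)
        if called_keys
        else float("nan")
    )
    return df


def run_end_to_end(config: PipelineConfig, out_dir) -> PipelineResult:
    """Run the full pooled-discovery workflow into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    t0 = stage("simulate: genome")
    genome, models = generate_genome(config.sim)
    paths["genome"] = out / "genome.fa"
    paths["models"] = out / "models.gff3"
    write_fasta([genome], paths["genome"])
    write_gff3(models, paths["models"])

    truth: Dict[str, TruthSet] = {}
    calls: Dict[str, list] = {}
    ref_meta = {genome.contig_id: len(genome)}
    for pool in (POOL_LOW, POOL_HIGH):
        stage(f"simulate+call: pool {pool}")
        _, pool_truth = mutagenize_pool(genome, models, config.sim, pool)
        truth[pool] = pool_truth
        pileup_path = out / f"pool_{pool}.pileup"
        write_pileup(
            simulate_pileup(genome, pool_truth, config.sim), pileup_path
        )
        paths[f"pileup_{pool}"] = pileup_path
        sites = read_pileup(
            pileup_path,
            min_baseq=config.caller.min_baseq,
            min_mapq=config.caller.min_mapq,
        )
        calls[pool] = call_pool(
            sites, config.caller, pool_id=pool, reference=genome
        )
        vcf_path = out / f"calls_{pool}.vcf"
        write_vcf(calls[pool], vcf_path, ref_meta)
        paths[f"vcf_{pool}"] = vcf_path
        pool_truth.write_tsv(out / f"truth_{pool}.tsv")
        paths[f"truth_{pool}"] = out / f"truth_{pool}.tsv"

    stage("compare + annotate specifics")
    comparison = compare_pools(calls[POOL_LOW], calls[POOL_HIGH])
    annotated_specific = {}
    for pool, specific in (
        (POOL_LOW, comparison.specific_low),
        (POOL_HIGH, comparison.specific_high),
    ):
        subset = [c for c in calls[pool] if c.key in specific]
        annotated = annotate_set(
            subset, models, genome, window_bp=config.window_bp
        )
        annotated_specific[pool] = annotated
        tsv = out / f"annotated_specific_{pool}.tsv"
        write_annotated_tsv(annotated, tsv)
        paths[f"annotated_{pool}"] = tsv

    summary = summarize_categories(
        annotated_specific[POOL_LOW], annotated_specific[POOL_HIGH]
    )
    paths["summary"] = out / "category_summary.tsv"
    summary.write_tsv(paths["summary"])

    stage("enrichment")
    study = affected_genes(
        annotated_specific[POOL_LOW], annotated_specific[POOL_HIGH]
    )
    background = {m.gene_id: m.category_label for m in models}
    enrich_results = []
    if study:
        enrich_results = fisher_enrichment(
            study,
            background,
            cutoff=config.enrich_cutoff,
            cutoff_on=config.enrich_cutoff_on,
        )
    paths["enrichment"] = out / "enrichment.tsv"
    enrichment_frame(enrich_results).to_csv(
        paths["enrichment"], sep="\t", index=False
    )

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(config.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("done in %.1f s", time.perf_counter() - t0)

    return PipelineResult(
        genome=genome,
        models=models,
        truth=truth,
        calls=calls,
        annotated_specific=annotated_specific,
        comparison=comparison,
        summary=summary,
        enrichment=enrich_results,
        paths=paths,
    )
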