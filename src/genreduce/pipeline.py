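"""End-to-end orchestration of the genome-reduction design pipeline.

``run_pipeline`` chains the stages -- classification, region selection,
plan ordering, sequential deletion with ledger accounting, construct
design, and fermentation kinetics -- from a single config, writing all
tabular outputs (TSV/BED/FASTA) plus a run log into the output directory.
Every stage output is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import ClassificationConfig, classify_genome, vote_histogram
from .constructs import DesignConfig, design_arms, design_primers
from .fermentation import rate_table, read_tidy_csv
from .genome_model import Genome, read_genome, read_proteome, write_bed, write_fasta
from .ledger import apply_plan, ledger_table
from .regions import (
    RegionCriteria,
    filter_regions,
    find_candidate_runs,
    order_plan,
    plan_table,
    read_cluster_table,
)

logger = logging.getLogger("genreduce")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    annotation: str = ""
    reference_proteome: str = ""
    panel_fastas: list[str] = field(default_factory=list)
    clusters_tsv: str = ""
    fermentation_csv: str = ""
    fermentation_window: tuple[float, float] = (14.0, 24.0)
    outdir: str = "pipeline_out"
    seed: int = 0
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    criteria: RegionCriteria = field(default_factory=RegionCriteria)
    design: DesignConfig = field(default_factory=DesignConfig)

    def validate(self) -> None:
        if self.panel_fastas and self.classification.essential_votes_min > len(
            self.panel_fastas
        ):
            raise ValueError(
                f"essential_votes_min {self.classification.essential_votes_min} "
                f"exceeds the {len(self.panel_fastas)} supplied panels"
            )


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        try:
            return asdict(o)
        except TypeError:
            return str(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    genome: Genome | None = None,
    reference: dict[str, str] | None = None,
    panels: list[dict[str, str]] | None = None,
) -> dict[str, object]:
    """Run every stage and write the output bundle.

    In-memory inputs (``genome``, ``reference``, ``panels``) take
    precedence over the file paths in the config, which lets callers feed
    simulated bundles without touching disk.  Any stage failure aborts
    with the stage named in the raised error.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log_lines = [f"genreduce {__version__}", f"config_hash {_config_hash(config)}"]

    results: dict[str, object] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        log_lines.append(f"stage {name}")

    try:
        stage("load")
        if genome is None:
            genome = read_genome(config.genome_fasta, config.annotation)
        if reference is None and config.reference_proteome:
            reference = read_proteome(config.reference_proteome)
        if panels is None:
            panels = [read_proteome(p) for p in config.panel_fastas]
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    try:
        stage("classify")
        statuses = classify_genome(genome, reference, panels, config.classification)
        statuses.to_csv(out / "classification.tsv", sep="\t", index=False)
        vote_histogram(statuses).to_csv(out / "vote_histogram.tsv", sep="\t", index=False)
        results["classification"] = statuses
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    try:
        stage("select-regions")
        runs = find_candidate_runs(statuses, genome)
        clusters = (
            read_cluster_table(config.clusters_tsv) if config.clusters_tsv else None
        )
        candidates = filter_regions(
            runs, config.criteria, genome, clusters=clusters, statuses=statuses
        )
        plan = order_plan(candidates, genome.length)
        pt = plan_table(plan)
        pt.to_csv(out / "deletion_plan.tsv", sep="\t", index=False)
        write_bed([r.interval for r in plan.regions], out / "deletion_plan.bed", genome.name)
        results["plan"] = plan
    except Exception as exc:
        raise RuntimeError(f"stage 'select-regions' failed: {exc}") from exc

    try:
        stage("apply")
        reduced, rows, lift = apply_plan(genome, plan)
        ledger_table(rows).to_csv(out / "deletion_ledger.tsv", sep="\t", index=False)
        write_fasta(reduced.name, reduced.sequence, out / "reduced_genome.fna")
        write_bed(lift.intervals, out / "deleted_regions.bed", genome.name)
        results["reduced"] = reduced
        results["ledger"] = rows
        results["liftover"] = lift
    except Exception as exc:
        raise RuntimeError(f"stage 'apply' failed: {exc}") from exc

    try:
        stage("design-primers")
        primer_rows = []
        for region in plan.regions:
            arms = design_arms(genome, region.interval, config.design)
            primers = design_primers(arms, region.interval, genome, config.design)
            for p in primers:
                primer_rows.append(
                    dict(
                        region=region.name,
                        primer=p.name,
                        sequence=p.sequence,
                        tm_c=round(p.tm, 1),
                        strand=p.strand,
                        start=p.start,
                        end=p.end,
                    )
                )
        primer_df = pd.DataFrame(primer_rows)
        primer_df.to_csv(out / "primers.tsv", sep="\t", index=False)
        results["primers"] = primer_df
    except Exception as exc:
        raise RuntimeError(f"stage 'design-primers' failed: {exc}") from exc

    if config.fermentation_csv:
        try:
            stage("ferment-rates")
            series = read_tidy_csv(config.fermentation_csv)
            rates = rate_table(series, config.fermentation_window)
            rates.to_csv(out / "rate_table.tsv", sep="\t", index=False)
            results["rates"] = rates
        except Exception as exc:
            raise RuntimeError(f"stage 'ferment-rates' failed: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results
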