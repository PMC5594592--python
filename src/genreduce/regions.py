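"""Deletion-region selection: candidate runs, filtering, endpoint snapping, ordering.

Candidate deletion targets are maximal runs of consecutive genes that are
strain-specific and non-essential.  A run qualifies as a multiple-deletion
(MD) region when its snapped interval spans at least 15 kb and the run
holds more than 10 genes; curated secondary-metabolite clusters (e.g. a
2.5 kb hydrogen-cyanide operon) bypass the size filters but never the
no-essential rule.  Deletion endpoints are snapped into the intergenic
gaps flanking the run (midpoint rule), retracting inside the region when a
neighbouring gene overlaps the terminal gene of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import STRAIN_SPECIFIC
from .genome_model import Gene, Genome, Interval

__all__ = [
    "RegionCriteria",
    "RegionCandidate",
    "DeletionPlan",
    "find_candidate_runs",
    "filter_regions",
    "snap_endpoints",
    "order_plan",
    "read_cluster_table",
]

PRIORITY_CLASSES = ["secondary_metabolite_cluster", "metabolism_transport", "hypothetical"]

# annotation categories treated as functional (metabolism/transport tier)
_FUNCTIONAL_CATEGORIES = {
    "metabolism",
    "transport",
    "amino_acid_metabolism",
    "carbohydrate_metabolism",
    "inorganic_ion_transport",
    "signal_transduction",
}


@dataclass
class RegionCriteria:
    min_span_bp: int = 15_000
    min_gene_run: int = 11  # "more than 10 genes"
    allow_essential: bool = False  # fixed; kept for explicitness

    def __post_init__(self) -> None:
        if self.min_span_bp <= 0 or self.min_gene_run < 1:
            raise ValueError("criteria must be positive")
        if self.allow_essential:
            raise ValueError("essential genes can never be deleted")


@dataclass
class RegionCandidate:
    genes: list[str]  # contiguous locus tags, genome order
    interval: Interval  # snapped endpoints
    priority_class: str
    name: str = ""

    @property
    def span_bp(self) -> int:
        return self.interval.size

    @property
    def gene_count(self) -> int:
        return len(self.genes)


@dataclass
class DeletionPlan:
    regions: list[RegionCandidate]
    parent_genome_length: int

    def __post_init__(self) -> None:
        ivs = sorted((r.interval for r in self.regions), key=lambda i: i.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end >= b.start:
                raise ValueError(f"plan intervals overlap: {a} / {b}")

    @property
    def total_bp(self) -> int:
        return sum(r.span_bp for r in self.regions)


def find_candidate_runs(statuses: pd.DataFrame, genome: Genome) -> list[list[Gene]]:
    """Maximal runs of consecutive strain-specific, non-essential genes.

    A conserved or essential gene terminates a run.  ``statuses`` must hold
    one row per gene with columns ``locus_tag``, ``conservation``,
    ``essential``.
    """
    by_locus = statuses.set_index("locus_tag")
    missing = [g.locus_tag for g in genome.genes if g.locus_tag not in by_locus.index]
    if missing:
        raise ValueError(f"statuses missing loci: {missing[:5]}")
    runs: list[list[Gene]] = []
    current: list[Gene] = []
    for g in genome.genes:
        row = by_locus.loc[g.locus_tag]
        deletable = row["conservation"] == STRAIN_SPECIFIC and not bool(row["essential"])
        if deletable:
            current.append(g)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def snap_endpoints(run: list[Gene], genome: Genome) -> Interval:
    """Snap a run's deletion endpoints into the flanking intergenic gaps.

    Left endpoint: midpoint of the gap between the run's first gene and its
    left neighbour (position 1 if the run starts the genome).  When the
    neighbour overlaps the run's first gene there is no gap; the endpoint
    retracts to the first base of the run not covered by the neighbour.
    The right endpoint is symmetric.
    """
    if not run:
        raise ValueError("empty run")
    first, last = run[0], run[-1]
    in_run = {g.locus_tag for g in run}
    left_nb = None
    right_nb = None
    for g in genome.genes:
        if g.locus_tag in in_run:
            continue
        if g.end < first.start or (g.start < first.start and g.end >= first.start):
            if left_nb is None or g.end > left_nb.end:
                left_nb = g
        if g.start > last.end or (g.end > last.end and g.start <= last.end):
            if right_nb is None or g.start < right_nb.start:
                right_nb = g

    if left_nb is None:
        left = 1
    elif left_nb.end >= first.start:  # overlap: retract inside the region
        left = left_nb.end + 1
    elif left_nb.end == first.start - 1:  # abutting, no gap
        left = first.start
    else:
        left = (left_nb.end + first.start) // 2

    if right_nb is None:
        right = genome.length
    elif right_nb.start <= last.end:  # overlap: retract
        right = right_nb.start - 1
    elif right_nb.start == last.end + 1:
        right = last.end
    else:
        right = (last.end + right_nb.start) // 2

    label = f"{first.locus_tag}-{last.locus_tag}" if len(run) > 1 else first.locus_tag
    return Interval(left, right, label)


def _classify_run(run: list[Gene]) -> str:
    cats = {g.category.lower() for g in run if g.category}
    if cats & _FUNCTIONAL_CATEGORIES:
        return "metabolism_transport"
    return "hypothetical"


def read_cluster_table(path) -> list[tuple[str, str, str]]:
    """Curated clusters as a 3-column TSV: name, first_locus, last_locus."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"cluster table rows need 3 columns: {line!r}")
            rows.append((fields[0], fields[1], fields[2]))
    return rows


def filter_regions(
    runs: list[list[Gene]],
    criteria: RegionCriteria,
    genome: Genome,
    clusters: list[tuple[str, str, str]] | None = None,
    statuses: pd.DataFrame | None = None,
) -> list[RegionCandidate]:
    """Apply the size filters; curated clusters bypass them.

    A run qualifies iff its snapped span >= ``min_span_bp`` and it holds at
    least ``min_gene_run`` genes.  ``clusters`` entries (name, first locus,
    last locus) are accepted regardless of size, tagged as
    secondary-metabolite clusters; a curated cluster overlapping an
    essential gene is a hard error.
    """
    essential_loci: set[str] = set()
    if statuses is not None:
        essential_loci = set(statuses.loc[statuses["essential"], "locus_tag"])

    candidates: list[RegionCandidate] = []
    cluster_loci: set[str] = set()
    for name, first_locus, last_locus in clusters or []:
        first, last = genome.gene(first_locus), genome.gene(last_locus)
        run = [g for g in genome.genes if first.start <= g.start <= last.start]
        for g in run:
            if g.locus_tag in essential_loci:
                raise ValueError(
                    f"curated cluster {name} overlaps essential gene {g.locus_tag}"
                )
        cluster_loci.update(g.locus_tag for g in run)
        candidates.append(
            RegionCandidate(
                genes=[g.locus_tag for g in run],
                interval=snap_endpoints(run, genome),
                priority_class="secondary_metabolite_cluster",
                name=name,
            )
        )

    for run in runs:
        if any(g.locus_tag in cluster_loci for g in run):
            continue  # already covered by a curated cluster
        if len(run) < criteria.min_gene_run:
            continue
        interval = snap_endpoints(run, genome)
        if interval.size < criteria.min_span_bp:
            continue
        candidates.append(
            RegionCandidate(
                genes=[g.locus_tag for g in run],
                interval=interval,
                priority_class=_classify_run(run),
            )
        )
    return candidates


def order_plan(
    candidates: list[RegionCandidate], parent_genome_length: int
) -> DeletionPlan:
    """Stable sort by (priority class, genome position); names MD1, MD2, ...

    Secondary-metabolite clusters come first, then metabolism/transport
    regions, finally regions of unknown function.
    """
    rank = {c: i for i, c in enumerate(PRIORITY_CLASSES)}
    ordered = sorted(
        candidates, key=lambda r: (rank.get(r.priority_class, len(rank)), r.interval.start)
    )
    named = []
    for i, r in enumerate(ordered, 1):
        named.append(
            RegionCandidate(
                genes=r.genes,
                interval=Interval(r.interval.start, r.interval.end, f"MD{i}"),
                priority_class=r.priority_class,
                name=f"MD{i}",
            )
        )
    return DeletionPlan(regions=named, parent_genome_length=parent_genome_length)


def plan_table(plan: DeletionPlan) -> pd.DataFrame:
    """TSV-ready summary: name, span, gene count, class, gene list."""
    return pd.DataFrame(
        dict(
            name=r.name,
            start=r.interval.start,
            end=r.interval.end,
            span_bp=r.span_bp,
            gene_count=r.gene_count,
            priority_class=r.priority_class,
            genes=",".join(r.genes),
        )
        for r in plan.regions
    )
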