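"""Sequential deletion accounting: apply a plan, track cumulative statistics,
remap coordinates, and emit the reduced genome.

This reproduces the bookkeeping of a multiple-deletion-series (MDS)
construction: step i removes region MD(i) from the strain carrying
MD1..MD(i-1), and the ledger records per-step bp, cumulative bp, and the
cumulative percentage of the parent genome (rounded half-up to two
decimals).  All plan intervals are expressed in PARENT coordinates; the
composition into post-deletion coordinates is internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genome_model import Gene, Genome, Interval
from .regions import DeletionPlan

__all__ = [
    "LedgerRow",
    "LiftoverMap",
    "DELETED",
    "apply_plan",
    "liftover",
    "ledger_from_step_sizes",
    "ledger_table",
]


def _round_half_up(x: float | Decimal, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LedgerRow:
    mutant_name: str  # MDS1, MDS2, ...
    step_deletion_bp: int
    cumulative_deletion_bp: int
    cumulative_percent: float  # of parent genome, 2 dp, half-up
    genomic_loci: str = ""
    description: str = ""


@dataclass(frozen=True)
class Deleted:
    """Marker returned by liftover for positions inside a deleted region."""

    region: str


DELETED = Deleted


@dataclass
class LiftoverMap:
    """Ordered, disjoint deleted intervals in parent coordinates."""

    intervals: list[Interval] = field(default_factory=list)
    parent_length: int = 0

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda i: i.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.end >= b.start:
                raise ValueError("liftover intervals overlap")


def liftover(position: int, lift: LiftoverMap) -> int | Deleted:
    """Map a parent coordinate onto the reduced genome.

    Returns the shifted position, or a :class:`Deleted` marker naming the
    region when the position falls inside a deleted interval.
    """
    if not (1 <= position <= lift.parent_length):
        raise ValueError(f"position {position} outside [1, {lift.parent_length}]")
    shift = 0
    for iv in lift.intervals:
        if iv.contains(position):
            return Deleted(iv.label)
        if iv.end < position:
            shift += iv.size
    return position - shift


def _cumulative_rows(
    steps: list[tuple[str, int, str, str]], parent_length: int
) -> list[LedgerRow]:
    rows, cum = [], 0
    for i, (name, size, loci, desc) in enumerate(steps, 1):
        cum += size
        pct = _round_half_up(Decimal(100 * cum) / Decimal(parent_length))
        rows.append(
            LedgerRow(
                mutant_name=name or f"MDS{i}",
                step_deletion_bp=size,
                cumulative_deletion_bp=cum,
                cumulative_percent=pct,
                genomic_loci=loci,
                description=desc,
            )
        )
    return rows


def ledger_from_step_sizes(
    step_sizes: list[int],
    parent_length: int,
    loci: list[str] | None = None,
    descriptions: list[str] | None = None,
) -> list[LedgerRow]:
    """Ledger arithmetic from bare per-step deletion sizes.

    Useful to recompute a published deletion series from its printed step
    sizes without the underlying sequence.
    """
    n = len(step_sizes)
    loci = loci or [""] * n
    descriptions = descriptions or [""] * n
    steps = [("", s, l, d) for s, l, d in zip(step_sizes, loci, descriptions)]
    return _cumulative_rows(steps, parent_length)


def apply_plan(
    genome: Genome, plan: DeletionPlan
) -> tuple[Genome, list[LedgerRow], LiftoverMap]:
    """Apply every deletion of the plan to the parent genome.

    Retained genes shift left by the total deleted bp before them; a plan
    interval that cuts a retained gene is a hard error (endpoints are meant
    to be snapped into intergenic sequence).  The returned ledger has one
    row per step with mutant names MDS1..MDSn.
    """
    if plan.parent_genome_length != genome.length:
        raise ValueError(
            f"plan parent length {plan.parent_genome_length} != genome length {genome.length}"
        )
    ivs = sorted((r.interval for r in plan.regions), key=lambda i: i.start)
    for iv in ivs:
        if iv.end > genome.length:
            raise ValueError(f"interval {iv} outside the genome")
    deleted_loci: set[str] = set()
    for r in plan.regions:
        deleted_loci.update(r.genes)
    for g in genome.genes:
        for iv in ivs:
            if iv.overlaps(g.interval):
                if g.locus_tag not in deleted_loci:
                    raise ValueError(
                        f"deletion {iv.label} would cut retained gene {g.locus_tag}"
                    )
                if not (iv.start <= g.start and g.end <= iv.end):
                    raise ValueError(
                        f"deletion {iv.label} only partially covers gene {g.locus_tag}"
                    )

    # reduced sequence: parent minus intervals
    keep_parts: list[str] = []
    pos = 1
    for iv in ivs:
        keep_parts.append(genome.sequence[pos - 1 : iv.start - 1])
        pos = iv.end + 1
    keep_parts.append(genome.sequence[pos - 1 :])
    reduced_seq = "".join(keep_parts)

    lift = LiftoverMap(intervals=list(ivs), parent_length=genome.length)
    new_genes = []
    for g in genome.genes:
        if g.locus_tag in deleted_loci:
            continue
        ns, ne = liftover(g.start, lift), liftover(g.end, lift)
        assert isinstance(ns, int) and isinstance(ne, int)
        new_genes.append(
            Gene(
                locus_tag=g.locus_tag,
                start=ns,
                end=ne,
                strand=g.strand,
                product=g.product,
                protein=g.protein,
                category=g.category,
            )
        )
    reduced = Genome(name=f"{genome.name}_reduced", sequence=reduced_seq, genes=new_genes)

    steps = [
        (f"MDS{i}", r.span_bp, r.interval.label, r.priority_class)
        for i, r in enumerate(plan.regions, 1)
    ]
    rows = _cumulative_rows(steps, genome.length)
    return reduced, rows, lift


def ledger_table(rows: list[LedgerRow]) -> pd.DataFrame:
    """Ledger as a DataFrame mirroring the standard column order."""
    return pd.DataFrame(
        dict(
            mutant=r.mutant_name,
            multiple_deletion_bp=r.step_deletion_bp,
            cumulative_deletion_bp=r.cumulative_deletion_bp,
            cumulative_deletion_percent=f"{r.cumulative_percent:.2f}",
            genomic_loci=r.genomic_loci,
            description=r.description,
        )
        for r in rows
    )
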