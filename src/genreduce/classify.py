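"""Gene classification: comparative subtraction and consensus essentiality voting.

Every protein-coding gene of the target genome is labelled

* ``conserved`` vs ``strain_specific`` by in-silico subtractive
  hybridization against a reference proteome (best hit must reach the
  homology-value cutoff, default H >= 0.42 at E < 1e-5), and
* ``essential`` vs non-essential by a consensus vote across curated
  essential-gene panels: a panel votes yes when the gene's best hit in it
  reaches >= 35% identity at E <= 1e-10, and the gene is called essential
  when at least 8 of the 15 panels vote yes (all thresholds configurable).

Genes lacking a protein (RNA genes) are labelled strain_specific and
non-essential and flagged, since the whole pipeline is protein-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import ScoringParams, best_hits, compute_h
from .genome_model import AlignmentHit, Gene, Genome

__all__ = [
    "ClassificationConfig",
    "GeneStatus",
    "subtract_genomes",
    "vote_essentiality",
    "classify_genome",
    "vote_histogram",
]

CONSERVED = "conserved"
STRAIN_SPECIFIC = "strain_specific"


@dataclass
class ClassificationConfig:
    """Thresholds for subtraction and essentiality voting."""

    h_cutoff: float = 0.42
    subtraction_evalue_max: float = 1e-5
    essential_identity_min: float = 35.0
    essential_evalue_max: float = 1e-10
    essential_votes_min: int = 8
    panel_count: int = 15
    essential_coverage_min: float = 0.0  # optional; off by default
    coverage_on: str = "query"
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if not (0.0 < self.h_cutoff <= 1.0):
            raise ValueError("h_cutoff must be in (0, 1]")
        if not (1 <= self.essential_votes_min <= self.panel_count):
            raise ValueError(
                f"essential_votes_min {self.essential_votes_min} outside "
                f"[1, {self.panel_count}]"
            )


@dataclass
class GeneStatus:
    locus_tag: str
    conservation: str = STRAIN_SPECIFIC
    essential_votes: int = 0
    essential: bool = False
    has_protein: bool = True
    best_subtraction_hit: AlignmentHit | None = None
    best_panel_hits: dict[int, AlignmentHit] = field(default_factory=dict)


def _hit_qualifies_subtraction(hit: AlignmentHit, cfg: ClassificationConfig) -> bool:
    h = hit.h_value
    if h is None:
        h = compute_h(hit, coverage_on=cfg.coverage_on)
    return h >= cfg.h_cutoff and hit.evalue < cfg.subtraction_evalue_max


def _best_per_query(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.score > cur.score
            or (h.score == cur.score and h.evalue < cur.evalue)
            or (
                h.score == cur.score
                and h.evalue == cur.evalue
                and h.subject_id < cur.subject_id
            )
        ):
            best[h.query_id] = h
    return best


def subtract_genomes(
    target: Genome,
    reference_proteome: dict[str, str],
    cfg: ClassificationConfig | None = None,
    hits: list[AlignmentHit] | None = None,
) -> dict[str, str]:
    """Conservation label per locus tag.

    A gene is conserved iff its best reference hit satisfies H >= h_cutoff
    and E < subtraction_evalue_max; genes without a qualifying (or any) hit
    are strain-specific.  Precomputed hits (e.g. an external BLASTP run
    loaded via ``read_hit_table``) may be supplied; otherwise the built-in
    aligner is used.
    """
    cfg = cfg or ClassificationConfig()
    if not reference_proteome:
        raise ValueError("reference proteome is empty")
    proteome = target.proteome()
    if hits is None:
        best = best_hits(proteome, reference_proteome, cfg.scoring)
    else:
        best = _best_per_query(hits)
    labels: dict[str, str] = {}
    for g in target.genes:
        hit = best.get(g.locus_tag) if g.protein else None
        labels[g.locus_tag] = (
            CONSERVED
            if hit is not None and _hit_qualifies_subtraction(hit, cfg)
            else STRAIN_SPECIFIC
        )
    return labels


def _panel_vote(hit: AlignmentHit | None, cfg: ClassificationConfig) -> bool:
    if hit is None:
        return False
    if hit.identity < cfg.essential_identity_min:
        return False
    if hit.evalue > cfg.essential_evalue_max:
        return False
    if cfg.essential_coverage_min > 0 and hit.qlen > 0:
        if hit.aln_len / hit.qlen < cfg.essential_coverage_min:
            return False
    return True


def vote_essentiality(
    gene: Gene,
    panels: list[dict[str, str]],
    cfg: ClassificationConfig | None = None,
    hits: list[dict[str, AlignmentHit]] | None = None,
) -> GeneStatus:
    """Consensus essentiality call for one gene across the panels.

    Each panel contributes at most one vote -- the best hit in that panel
    must reach the identity and E-value thresholds.  ``hits``, when given,
    is a per-panel mapping of locus tag to best hit.
    """
    cfg = cfg or ClassificationConfig()
    if not panels:
        raise ValueError("no essential-gene panels supplied")
    if cfg.essential_votes_min > len(panels):
        raise ValueError(
            f"essential_votes_min {cfg.essential_votes_min} exceeds panel count {len(panels)}"
        )
    status = GeneStatus(locus_tag=gene.locus_tag, has_protein=bool(gene.protein))
    if not gene.protein:
        return status
    for i, panel in enumerate(panels):
        if hits is not None:
            hit = hits[i].get(gene.locus_tag)
        else:
            hit = best_hits({gene.locus_tag: gene.protein}, panel, cfg.scoring).get(
                gene.locus_tag
            )
        if hit is not None:
            status.best_panel_hits[i] = hit
        if _panel_vote(hit, cfg):
            status.essential_votes += 1
    status.essential = status.essential_votes >= cfg.essential_votes_min
    return status


def classify_genome(
    target: Genome,
    reference_proteome: dict[str, str],
    panels: list[dict[str, str]],
    cfg: ClassificationConfig | None = None,
    subtraction_hits: list[AlignmentHit] | None = None,
    panel_hits: list[list[AlignmentHit]] | None = None,
) -> pd.DataFrame:
    """Full per-gene classification table.

    Returns one row per gene with columns ``locus_tag``, ``conservation``,
    ``essential_votes``, ``essential``, ``has_protein`` plus best-hit
    summary fields.  The partition is exhaustive: every gene is either
    conserved or strain_specific.
    """
    cfg = cfg or ClassificationConfig()
    if len(panels) != cfg.panel_count:
        cfg = ClassificationConfig(
            h_cutoff=cfg.h_cutoff,
            subtraction_evalue_max=cfg.subtraction_evalue_max,
            essential_identity_min=cfg.essential_identity_min,
            essential_evalue_max=cfg.essential_evalue_max,
            essential_votes_min=cfg.essential_votes_min,
            panel_count=len(panels),
            essential_coverage_min=cfg.essential_coverage_min,
            coverage_on=cfg.coverage_on,
            scoring=cfg.scoring,
        )
    labels = subtract_genomes(target, reference_proteome, cfg, subtraction_hits)

    # batch the per-panel searches for speed, then vote per gene
    proteome = target.proteome()
    per_panel_best: list[dict[str, AlignmentHit]] = []
    for i, panel in enumerate(panels):
        if panel_hits is not None:
            per_panel_best.append(_best_per_query(panel_hits[i]))
        else:
            per_panel_best.append(best_hits(proteome, panel, cfg.scoring))

    rows = []
    for g in target.genes:
        status = vote_essentiality(g, panels, cfg, hits=per_panel_best)
        rows.append(
            dict(
                locus_tag=g.locus_tag,
                conservation=labels[g.locus_tag],
                essential_votes=status.essential_votes,
                essential=status.essential,
                has_protein=bool(g.protein),
            )
        )
    return pd.DataFrame(rows)


def vote_histogram(table: pd.DataFrame) -> pd.DataFrame:
    """Histogram of essentiality votes (rows: vote count 0..max, n genes)."""
    counts = table["essential_votes"].value_counts().sort_index()
    return counts.rename_axis("votes").reset_index(name="n_genes")
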