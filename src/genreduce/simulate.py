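"""Synthetic data with known ground truth for every pipeline stage.

``generate_genome_pair`` emulates a target/reference genome pair for the
subtractive pipeline: a bacterial chromosome with lognormal gene lengths,
a known conserved/strain-specific partition (conserved genes appear in the
reference proteome mutated to a target identity), planted essential genes
shared with a configurable number of the 15 essential-gene panels, and
planted deletable runs (contiguous strain-specific, non-essential genes
meeting a span floor).  Background strain-specific runs are capped well
below the deletion-region gene floor so the planted regions are the only
qualifying candidates and recovery can be scored exactly.

``generate_fermentation`` emulates a phenazine fermentation: exponential
biomass X(t) = X0*exp(mu*t), growth-associated production dP_i/dt = q_i*X,
and a first-order abiotic conversion of 2-OH-PCA into 2-OH-PHZ at rate k
(the hydroxy acid loses its carboxyl group spontaneously, with no enzyme
involved).  Trajectories use the closed-form solution of this linear
system; measurement noise is multiplicative lognormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .fermentation import ANALYTES, MOLAR_MASSES, TimeSeries
from .genome_model import Gene, Genome, write_annotation, write_fasta

__all__ = [
    "GenomeSimConfig",
    "FermSimConfig",
    "GenomePairBundle",
    "generate_genome_pair",
    "generate_fermentation",
    "phenazine_closed_form",
    "write_bundle",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

# bacterial-code codons per residue (TAA used as the stop)
_CODONS: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}


@dataclass
class GenomeSimConfig:
    """Layout and divergence parameters for the synthetic genome pair."""

    n_genes: int = 200
    gene_length_median_bp: int = 900  # lognormal median
    gene_length_sigma: float = 0.25
    gap_min_bp: int = 60
    gap_max_bp: int = 250
    frac_conserved: float = 0.3
    conserved_identity: float = 0.80  # per-residue identity of reference copies
    n_essential_planted: int = 20
    essential_panel_votes: int = 10  # of panel_count panels receive each essential
    essential_panel_identity: float = 0.60
    panel_count: int = 15
    panel_decoys: int = 10  # random proteins per panel
    reference_decoys: int = 20
    planted_regions: list[tuple[int, int]] = field(
        default_factory=lambda: [(12, 16_000)]
    )  # (gene_count, min_span_bp)
    max_background_run: int = 4  # cap on accidental strain-specific runs
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_conserved <= 1.0):
            raise ValueError("frac_conserved outside [0, 1]")
        planted = sum(n for n, _ in self.planted_regions)
        if planted + self.n_essential_planted + 2 * len(self.planted_regions) > self.n_genes:
            raise ValueError("layout infeasible: too few genes for the planted structure")
        if not (0 <= self.essential_panel_votes <= self.panel_count):
            raise ValueError("essential_panel_votes outside [0, panel_count]")


@dataclass
class GenomePairBundle:
    target: Genome
    reference_proteome: dict[str, str]
    panels: list[dict[str, str]]
    truth: pd.DataFrame  # locus_tag, conserved, essential, region


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "".join(rng.choice(list(_AA), size=n_aa))


def _mutate_to_identity(
    rng: np.random.Generator, protein: str, identity: float
) -> str:
    """Substitute residues so the copy matches ``protein`` at ~identity."""
    n_sub = round((1.0 - identity) * len(protein))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    out = list(protein)
    for p in positions:
        choices = [a for a in _AA if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = ["ATG"]
    for aa in protein[1:]:
        opts = _CODONS[aa]
        codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


def _draw_gene_length_aa(rng: np.random.Generator, cfg: GenomeSimConfig) -> int:
    bp = rng.lognormal(np.log(cfg.gene_length_median_bp), cfg.gene_length_sigma)
    return max(60, int(bp) // 3)  # protein length incl. start, excl. stop


def generate_genome_pair(cfg: GenomeSimConfig) -> GenomePairBundle:
    """Build the target genome, reference proteome, panels, and truth table.

    Deterministic for a fixed config (single seeded generator drives every
    draw).  The genes flanking each planted region are forced conserved so
    each region is a maximal strain-specific run; background runs are
    capped at ``max_background_run`` genes.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    # --- assign planted region slots (with conserved guards on both sides)
    region_of = [""] * n
    guard = [False] * n
    slots_needed = [(f"R{i+1}", count, span) for i, (count, span) in enumerate(cfg.planted_regions)]
    cursor = 2
    for name, count, _span in slots_needed:
        start = cursor
        if start + count + 1 >= n:
            raise ValueError("layout infeasible: planted regions do not fit")
        for j in range(start, start + count):
            region_of[j] = name
        guard[start - 1] = True
        guard[start + count] = True
        cursor = start + count + int(max(4, n // (len(slots_needed) + 1) - count))
        cursor = min(cursor, n - 1)

    # --- conserved / essential assignment outside regions
    conserved = [False] * n
    in_region = [bool(r) for r in region_of]
    free = [i for i in range(n) if not in_region[i] and not guard[i]]
    n_conserved_target = round(cfg.frac_conserved * n)
    for i in range(n):
        if guard[i]:
            conserved[i] = True
    picks = rng.choice(free, size=min(len(free), max(0, n_conserved_target - sum(conserved))), replace=False)
    for i in picks:
        conserved[i] = True
    # cap accidental strain-specific background runs
    run = 0
    for i in range(n):
        if in_region[i]:
            run = 0
            continue
        if conserved[i]:
            run = 0
        else:
            run += 1
            if run > cfg.max_background_run:
                conserved[i] = True
                run = 0

    essential = [False] * n
    conserved_free = [i for i in range(n) if conserved[i] and not in_region[i]]
    if cfg.n_essential_planted > len(conserved_free):
        raise ValueError("layout infeasible: not enough conserved genes for essentials")
    for i in rng.choice(conserved_free, size=cfg.n_essential_planted, replace=False):
        essential[i] = True

    # --- per-region gene lengths sized to clear the span floor
    length_aa = [_draw_gene_length_aa(rng, cfg) for _ in range(n)]
    for name, count, span in slots_needed:
        idxs = [i for i in range(n) if region_of[i] == name]
        # span is met by genes alone (gaps only add margin)
        per_gene_aa = int(np.ceil(span * 1.05 / count / 3)) + 2
        for i in idxs:
            length_aa[i] = max(length_aa[i], per_gene_aa)

    # --- sequences
    proteins = [_random_protein(rng, length_aa[i]) for i in range(n)]
    genes: list[Gene] = []
    seq_parts: list[str] = []
    pos = 1
    for i in range(n):
        gap = int(rng.integers(cfg.gap_min_bp, cfg.gap_max_bp + 1))
        seq_parts.append("".join(rng.choice(list("ACGT"), size=gap)))
        pos += gap
        cds = _reverse_translate(rng, proteins[i])
        strand = "+" if rng.random() < 0.5 else "-"
        seq_parts.append(cds if strand == "+" else str(Seq(cds).reverse_complement()))
        start, end = pos, pos + len(cds) - 1
        category = "hypothetical"
        if region_of[i] and rng.random() < 0.3:
            category = "metabolism"
        genes.append(
            Gene(
                locus_tag=f"SYN_{i+1:05d}",
                start=start,
                end=end,
                strand=strand,
                product="synthetic protein",
                protein=proteins[i],
                category=category,
            )
        )
        pos = end + 1
    tail_gap = int(rng.integers(cfg.gap_min_bp, cfg.gap_max_bp + 1))
    seq_parts.append("".join(rng.choice(list("ACGT"), size=tail_gap)))
    target = Genome(name="synthetic_target", sequence="".join(seq_parts), genes=genes)

    # --- reference proteome: mutated copies of conserved genes + decoys
    reference: dict[str, str] = {}
    for i in range(n):
        if conserved[i]:
            reference[f"REF_{i+1:05d}"] = _mutate_to_identity(
                rng, proteins[i], cfg.conserved_identity
            )
    for d in range(cfg.reference_decoys):
        reference[f"REFDECOY_{d+1:04d}"] = _random_protein(
            rng, _draw_gene_length_aa(rng, cfg)
        )

    # --- essential-gene panels
    panels: list[dict[str, str]] = [dict() for _ in range(cfg.panel_count)]
    for i in range(n):
        if not essential[i]:
            continue
        chosen = rng.choice(cfg.panel_count, size=cfg.essential_panel_votes, replace=False)
        for p in chosen:
            panels[p][f"ESS_{i+1:05d}"] = _mutate_to_identity(
                rng, proteins[i], cfg.essential_panel_identity
            )
    for p in range(cfg.panel_count):
        for d in range(cfg.panel_decoys):
            panels[p][f"PANDECOY_{p+1:02d}_{d+1:03d}"] = _random_protein(
                rng, _draw_gene_length_aa(rng, cfg)
            )

    truth = pd.DataFrame(
        dict(
            locus_tag=[g.locus_tag for g in genes],
            conserved=conserved,
            essential=essential,
            region=region_of,
        )
    )
    return GenomePairBundle(target, reference, panels, truth)


def write_bundle(bundle: GenomePairBundle, outdir: str | Path) -> None:
    """Write the bundle in the exact dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.target.name, bundle.target.sequence, outdir / "target.fna")
    write_annotation(bundle.target, outdir / "target_annotation.tsv")
    with open(outdir / "reference_proteome.faa", "w") as fh:
        for name, seq in bundle.reference_proteome.items():
            fh.write(f">{name}\n{seq}\n")
    for i, panel in enumerate(bundle.panels, 1):
        with open(outdir / f"panel_{i:02d}.faa", "w") as fh:
            for name, seq in panel.items():
                fh.write(f">{name}\n{seq}\n")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# fermentation simulator


@dataclass
class FermSimConfig:
    """Planted kinetic parameters for a phenazine fermentation."""

    strain: str = "synthetic"
    mu_true: float = 0.1226  # 1/h
    q_true: dict[str, float] = field(
        default_factory=lambda: {"PCA": 0.0061, "2OHPCA": 0.0064, "2OHPHZ": 0.0008}
    )  # mmol/g/h
    x0: float = 0.5  # g/L at t = 0 of the window clock
    sample_times: tuple[float, ...] = (0.0, 14.0, 18.0, 21.0, 24.0)
    noise_cv: float = 0.0
    conversion_k: float = 0.0  # 1/h, abiotic 2-OH-PCA -> 2-OH-PHZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_true <= 0 or self.x0 <= 0:
            raise ValueError("mu and X0 must be positive")
        if any(q < 0 for q in self.q_true.values()) or self.conversion_k < 0:
            raise ValueError("rates must be non-negative")


def phenazine_closed_form(
    t: np.ndarray,
    mu: float,
    q: dict[str, float],
    x0: float,
    k: float = 0.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Exact trajectories of the linear production system, in mmol/L.

    X(t) = X0 e^{mu t};  dP_PCA/dt = q_PCA X;
    dP_2OHPCA/dt = q_2OHPCA X - k P_2OHPCA;
    dP_2OHPHZ/dt = q_2OHPHZ X + k P_2OHPCA.
    """
    t = np.asarray(t, dtype=float)
    x = x0 * np.exp(mu * t)
    growth_int = x0 * (np.exp(mu * t) - 1.0) / mu  # integral of X
    p_pca = q.get("PCA", 0.0) * growth_int
    q2, q3 = q.get("2OHPCA", 0.0), q.get("2OHPHZ", 0.0)
    if k == 0.0:
        p2 = q2 * growth_int
        p3 = q3 * growth_int
    else:
        p2 = q2 * x0 * (np.exp(mu * t) - np.exp(-k * t)) / (mu + k)
        p3 = q3 * growth_int + k * q2 * x0 / (mu + k) * (
            (np.exp(mu * t) - 1.0) / mu + (np.exp(-k * t) - 1.0) / k
        )
    return x, {"PCA": p_pca, "2OHPCA": p2, "2OHPHZ": p3}


def generate_fermentation(
    cfg: FermSimConfig, n_replicates: int = 1
) -> list[TimeSeries]:
    """Sampled fermentation course(s) with multiplicative lognormal noise.

    Concentrations are converted from mmol/L to mg/L with the phenazine
    molar masses.  With ``noise_cv`` = 0 the replicates are identical and
    equal to the closed-form trajectory, so the rate estimators recover
    the planted parameters exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.sample_times, dtype=float)
    x, p = phenazine_closed_form(t, cfg.mu_true, cfg.q_true, cfg.x0, cfg.conversion_k)
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    out = []
    for r in range(n_replicates):
        def noisy(values: np.ndarray) -> np.ndarray:
            if sigma == 0.0:
                return values.copy()
            z = rng.standard_normal(len(values))
            return values * np.exp(sigma * z - sigma**2 / 2.0)

        conc = {
            a: noisy(p[a] * MOLAR_MASSES.of(a)) for a in ANALYTES
        }
        out.append(
            TimeSeries(
                strain=cfg.strain if n_replicates == 1 else f"{cfg.strain}_rep{r+1}",
                times=t,
                biomass=noisy(x),
                concentrations=conc,
            )
        )
    return out


def fermentation_tidy_frame(series: list[TimeSeries]) -> pd.DataFrame:
    """Series -> the tidy CSV layout the fermentation reader accepts."""
    rows = []
    for s in series:
        for i, t in enumerate(s.times):
            for a in s.concentrations:
                rows.append(
                    dict(
                        strain=s.strain,
                        time_h=t,
                        biomass_g_per_L=s.biomass[i],
                        analyte=a,
                        conc_mg_per_L=s.concentrations[a][i],
                    )
                )
    return pd.DataFrame(rows)
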