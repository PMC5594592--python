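"""Homology-arm and primer design for markerless (sacB counter-selected) deletions.

For a deletion interval, a pK18mobsacB-style construct needs:

* upstream and downstream homology arms of 400-800 bp abutting the
  deletion endpoints exactly;
* four fusion-PCR primers: F1/R1 amplify the upstream arm and F2/R2 the
  downstream arm, with R1 and F2 sharing an 18-20 bp overlap so the two
  products fuse into the scarless junction by overlap-extension PCR, and
  F1/R2 carrying two distinct restriction sites (absent from the joined
  insert) at their 5' ends for cloning;
* a verification pair NF/NR annealing strictly inside the deleted
  fragment, which loses its template once the deletion is made.

The overlap tail is placed on F2 (its 5' end carries the 3' terminus of
the upstream arm); primer annealing regions are sized greedily from 20 nt
outward until the melting temperature falls in the configured window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome_model import Genome, Interval

__all__ = [
    "DesignConfig",
    "ArmPair",
    "Primer",
    "PrimerSet",
    "design_arms",
    "design_primers",
    "melting_temp",
    "simulate_overlap_pcr",
    "RESTRICTION_SITES",
]

# pK18mobsacB polylinker-compatible enzymes, in preference order
RESTRICTION_SITES: dict[str, str] = {
    "EcoRI": "GAATTC",
    "BamHI": "GGATCC",
    "HindIII": "AAGCTT",
    "PstI": "CTGCAG",
    "SalI": "GTCGAC",
    "XbaI": "TCTAGA",
}

_R = 1.987  # cal/(mol*K)

# unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K)
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class DesignConfig:
    min_arm: int = 400
    max_arm: int = 800
    target_arm: int = 600
    tm_min: float = 55.0
    tm_max: float = 65.0
    overlap_len: int = 20  # clamped to [18, 20]
    anneal_min: int = 18
    anneal_max: int = 30
    na_mM: float = 50.0  # monovalent salt
    primer_nM: float = 500.0  # total strand concentration
    verify_product_min: int = 300
    verify_product_max: int = 600
    enzymes: dict[str, str] = field(default_factory=lambda: dict(RESTRICTION_SITES))

    def __post_init__(self) -> None:
        if not (18 <= self.overlap_len <= 20):
            raise ValueError("overlap_len must be in [18, 20]")
        if self.min_arm > self.target_arm or self.target_arm > self.max_arm:
            raise ValueError("arm lengths must satisfy min <= target <= max")


@dataclass
class ArmPair:
    upstream_arm: str
    downstream_arm: str
    upstream_interval: Interval
    downstream_interval: Interval


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # full 5'->3' sequence including any tail/site
    anneal: str  # genome-annealing 3' portion
    strand: str
    start: int  # parent coordinates of the annealing region
    end: int
    tm: float


@dataclass
class PrimerSet:
    F1: Primer
    R1: Primer
    F2: Primer
    R2: Primer
    NF: Primer
    NR: Primer
    overlap_len: int
    sites: tuple[str, str]  # enzyme names on F1 and R2

    def __iter__(self):
        return iter([self.F1, self.R1, self.F2, self.R2, self.NF, self.NR])


def melting_temp(seq: str, na_mM: float = 50.0, strand_nM: float = 500.0) -> float:
    """Duplex melting temperature in degrees Celsius.

    Nearest-neighbor summation with unified parameters; the entropy gets
    the 0.368*(N-1)*ln[Na+] salt correction, and the concentration term is
    CT/4 for a non-self-complementary duplex.  Sequences shorter than
    14 nt fall back to the Wallace rule 2(A+T) + 4(G+C).
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence too short for a meaningful Tm")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous bases {sorted(bad)} not supported")
    if len(seq) < 14:
        return 2.0 * (seq.count("A") + seq.count("T")) + 4.0 * (
            seq.count("G") + seq.count("C")
        )
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        ih, is_ = _INIT_GC if end in "GC" else _INIT_AT
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN:
            pair = _revcomp(pair)
        h, s = _NN[pair]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM * 1e-3)
    ct = strand_nM * 1e-9
    return dh * 1000.0 / (ds + _R * math.log(ct / 4.0)) - 273.15


def design_arms(genome: Genome, interval: Interval, cfg: DesignConfig | None = None) -> ArmPair:
    """Homology arms abutting the deletion endpoints.

    Arms are cut at ``target_arm`` length and trimmed toward ``min_arm``
    when a flank is short; a flank below ``min_arm`` is an error.
    """
    cfg = cfg or DesignConfig()
    left_flank = interval.start - 1  # bp available upstream
    right_flank = genome.length - interval.end
    up_len = min(cfg.target_arm, left_flank)
    down_len = min(cfg.target_arm, right_flank)
    if up_len < cfg.min_arm:
        raise ValueError(
            f"upstream flank of {left_flank} bp is below the {cfg.min_arm} bp minimum"
        )
    if down_len < cfg.min_arm:
        raise ValueError(
            f"downstream flank of {right_flank} bp is below the {cfg.min_arm} bp minimum"
        )
    up_iv = Interval(interval.start - up_len, interval.start - 1, "upstream_arm")
    down_iv = Interval(interval.end + 1, interval.end + down_len, "downstream_arm")
    return ArmPair(
        upstream_arm=genome.subsequence(up_iv),
        downstream_arm=genome.subsequence(down_iv),
        upstream_interval=up_iv,
        downstream_interval=down_iv,
    )


def _anneal_lengths(cfg: DesignConfig):
    """Candidate lengths greedily outward from 20 nt, ties toward shorter."""
    lengths, seen = [], set()
    for delta in range(0, cfg.anneal_max - cfg.anneal_min + 1):
        for n in (20 - delta, 20 + delta):
            if cfg.anneal_min <= n <= cfg.anneal_max and n not in seen:
                seen.add(n)
                lengths.append(n)
    return lengths


def _try_fit_anneal(sub: str, from_start: bool, cfg: DesignConfig) -> str | None:
    for n in _anneal_lengths(cfg):
        if n > len(sub):
            continue
        cand = sub[:n] if from_start else sub[-n:]
        if cfg.tm_min <= melting_temp(cand, cfg.na_mM, cfg.primer_nM) <= cfg.tm_max:
            return cand
    return None


def _fit_anneal(sub: str, from_start: bool, cfg: DesignConfig) -> str:
    """Choose a prefix/suffix of ``sub`` whose Tm lies in the window.

    The annealing end of a junction primer is pinned to the deletion
    endpoint, so an in-window length may simply not exist (AT-rich ends
    never reach the floor; GC-rich ends start above the ceiling).  In
    that case fall back to the candidate whose Tm is closest to the
    window, preferring the greedy length order on ties, so that a design
    is always produced.
    """
    cand = _try_fit_anneal(sub, from_start, cfg)
    if cand is not None:
        return cand
    best, best_dist = None, math.inf
    for n in _anneal_lengths(cfg):
        if n > len(sub):
            continue
        c = sub[:n] if from_start else sub[-n:]
        tm = melting_temp(c, cfg.na_mM, cfg.primer_nM)
        dist = max(cfg.tm_min - tm, tm - cfg.tm_max, 0.0)
        if dist < best_dist:
            best, best_dist = c, dist
    if best is None:
        raise ValueError("no annealing region in the configured length range")
    return best


def _pick_sites(insert: str, cfg: DesignConfig) -> tuple[str, str]:
    """Earliest two enzymes in list order whose sites are absent from the insert."""
    free = [
        name
        for name, site in cfg.enzymes.items()
        if site not in insert and _revcomp(site) not in insert
    ]
    if len(free) < 2:
        conflicts = [n for n in cfg.enzymes if n not in free]
        raise ValueError(f"no usable restriction-site pair; conflicts: {conflicts}")
    return free[0], free[1]


def design_primers(
    arms: ArmPair,
    interval: Interval,
    genome: Genome,
    cfg: DesignConfig | None = None,
) -> PrimerSet:
    """The six primers of a markerless-deletion construct.

    F1/R1 amplify the upstream arm, F2/R2 the downstream arm; F2 carries a
    5' tail equal to the reverse complement of R1's annealing region
    (clamped to 18-20 nt) so that overlap-extension PCR with F1/R2 yields
    upstream_arm + downstream_arm exactly.  NF/NR amplify a 300-600 bp
    verification product wholly inside the deleted interval.
    """
    cfg = cfg or DesignConfig()
    up, down = arms.upstream_arm, arms.downstream_arm
    insert = up + down
    site_f1, site_r2 = _pick_sites(insert, cfg)

    f1_anneal = _fit_anneal(up, True, cfg)
    r1_anneal_sense = _fit_anneal(up, False, cfg)  # 3' terminus of the upstream arm
    f2_anneal = _fit_anneal(down, True, cfg)
    r2_anneal_sense = _fit_anneal(down, False, cfg)

    overlap = min(cfg.overlap_len, len(r1_anneal_sense))
    if overlap < 18:
        raise ValueError("R1 annealing region shorter than the 18 bp overlap floor")
    tail = up[-overlap:]  # == revcomp of the last `overlap` nt of R1

    ui, di = arms.upstream_interval, arms.downstream_interval
    f1 = Primer(
        "F1",
        cfg.enzymes[site_f1] + f1_anneal,
        f1_anneal,
        "+",
        ui.start,
        ui.start + len(f1_anneal) - 1,
        melting_temp(f1_anneal, cfg.na_mM, cfg.primer_nM),
    )
    r1 = Primer(
        "R1",
        _revcomp(r1_anneal_sense),
        _revcomp(r1_anneal_sense),
        "-",
        ui.end - len(r1_anneal_sense) + 1,
        ui.end,
        melting_temp(r1_anneal_sense, cfg.na_mM, cfg.primer_nM),
    )
    f2 = Primer(
        "F2",
        tail + f2_anneal,
        f2_anneal,
        "+",
        di.start,
        di.start + len(f2_anneal) - 1,
        melting_temp(f2_anneal, cfg.na_mM, cfg.primer_nM),
    )
    r2 = Primer(
        "R2",
        cfg.enzymes[site_r2] + _revcomp(r2_anneal_sense),
        _revcomp(r2_anneal_sense),
        "-",
        di.end - len(r2_anneal_sense) + 1,
        di.end,
        melting_temp(r2_anneal_sense, cfg.na_mM, cfg.primer_nM),
    )

    # verification pair strictly inside the deleted interval
    deleted = genome.subsequence(interval)
    pad = 10  # keep verification primers off the exact endpoints
    avail = len(deleted) - 2 * pad
    if avail < cfg.verify_product_min:
        raise ValueError(
            f"deleted interval of {len(deleted)} bp too small for a "
            f"{cfg.verify_product_min} bp verification product"
        )
    # NF may slide right from the left pad; NR slides so the product stays
    # in [verify_product_min, verify_product_max]
    nf_anneal, nf_offset = None, pad
    max_slide = max(0, avail - cfg.verify_product_min)
    for off in range(pad, pad + max_slide + 1, 5):
        nf_anneal = _try_fit_anneal(deleted[off : off + 40], True, cfg)
        if nf_anneal is not None:
            nf_offset = off
            break
    if nf_anneal is None:
        raise ValueError("no Tm-feasible NF primer inside the deleted interval")
    room = len(deleted) - pad - nf_offset  # bp available right of NF start
    nr_anneal_sense, product_len = None, 0
    hi = min(cfg.verify_product_max, room)
    for plen in range(hi, cfg.verify_product_min - 1, -5):
        end = nf_offset + plen  # exclusive index into `deleted`
        nr_anneal_sense = _try_fit_anneal(deleted[end - 40 : end], False, cfg)
        if nr_anneal_sense is not None:
            product_len = plen
            break
    if nr_anneal_sense is None:
        raise ValueError("no Tm-feasible NR primer inside the deleted interval")
    nf = Primer(
        "NF",
        nf_anneal,
        nf_anneal,
        "+",
        interval.start + nf_offset,
        interval.start + nf_offset + len(nf_anneal) - 1,
        melting_temp(nf_anneal, cfg.na_mM, cfg.primer_nM),
    )
    nr_end = interval.start + nf_offset + product_len - 1
    nr = Primer(
        "NR",
        _revcomp(nr_anneal_sense),
        _revcomp(nr_anneal_sense),
        "-",
        nr_end - len(nr_anneal_sense) + 1,
        nr_end,
        melting_temp(nr_anneal_sense, cfg.na_mM, cfg.primer_nM),
    )
    return PrimerSet(f1, r1, f2, r2, nf, nr, overlap, (site_f1, site_r2))


def simulate_overlap_pcr(arms: ArmPair, primers: PrimerSet) -> str:
    """In-silico overlap-extension PCR of the two arm products.

    PCR 1 (F1/R1) yields the upstream arm with the F1 site tag; PCR 2
    (F2/R2) yields the downstream arm with the F2 overlap tail and the R2
    site tag.  The products anneal via the shared R1/F2 overlap and extend
    into the fused insert.  Returns the fused sequence with the 5' tags
    stripped, which must equal upstream_arm + downstream_arm (the scarless
    junction template).
    """
    prod1 = primers.F1.sequence[: -len(primers.F1.anneal)] + arms.upstream_arm
    tail = primers.F2.sequence[: -len(primers.F2.anneal)]
    prod2 = tail + arms.downstream_arm
    if not prod1.endswith(tail):
        raise ValueError("R1/F2 overlap does not match the upstream-arm terminus")
    fused = prod1 + prod2[len(tail) :]
    # strip the F1 restriction tag to recover the genomic junction template
    tag = primers.F1.sequence[: -len(primers.F1.anneal)]
    return fused[len(tag) :]
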