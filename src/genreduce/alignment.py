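"""Pairwise protein comparison: local alignment, E-values and the H-value.

This is the built-in stand-in for a BLASTP search in the subtractive
pipeline.  It computes exact Smith-Waterman local alignments under affine
gap costs (a gap of length k costs ``gap_open + k * gap_extend``), converts
raw scores to bit scores with Karlin-Altschul statistics, and derives the
in-silico subtractive-hybridization homology value

    H = (identity / 100) * min(1, aln_len / qlen)

whose cutoff (0.42 by default downstream) separates conserved from
strain-specific genes.  Users with an external BLAST run can bypass this
module entirely through the 12-column hit-table reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import AlignmentHit

__all__ = [
    "ScoringParams",
    "smith_waterman",
    "estimate_evalue",
    "compute_h",
    "best_hits",
]

LN2 = math.log(2.0)


@dataclass
class ScoringParams:
    """Scoring scheme plus Karlin-Altschul statistics.

    Defaults are the conventional gapped-BLOSUM62 values (lambda = 0.267,
    K = 0.041, gap open 11 / extend 1).  The effective search space is the
    plain product of query and database residue counts; no edge correction
    is applied, as E-values here are only ever thresholded.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    K: float = 0.041
    search_space_m: int = 0
    search_space_n: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def bit_score(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.K)) / LN2


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # gap of length k costs open + k*extend (BLAST convention)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_alphabet(seq: str, alphabet: str, which: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{which} sequence has residues outside the matrix alphabet: {sorted(bad)}")


def smith_waterman(
    query: str, subject: str, params: ScoringParams | None = None
) -> AlignmentHit:
    """Best local alignment of two proteins under affine gap costs.

    Identity is matches / aligned columns (gaps included) * 100; the raw
    score is converted to bits via S' = (lambda*S - ln K) / ln 2.  The
    E-value is left at +inf until :func:`estimate_evalue` supplies a search
    space.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    params = params or ScoringParams()
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    _check_alphabet(query, alphabet, "query")
    _check_alphabet(subject, alphabet, "subject")

    alignments = aligner.align(query, subject)
    raw = alignments.score
    if raw <= 0:  # empty local alignment: report a null hit
        return AlignmentHit(
            query_id="query",
            subject_id="subject",
            identity=0.0,
            aln_len=1,
            qlen=len(query),
            slen=len(subject),
            score=params.bit_score(0.0),
        )
    best = alignments[0]
    counts = best.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / aln_len
    return AlignmentHit(
        query_id="query",
        subject_id="subject",
        identity=identity,
        aln_len=aln_len,
        qlen=len(query),
        slen=len(subject),
        score=params.bit_score(raw),
    )


def smith_waterman_score(query: str, subject: str, params: ScoringParams) -> float:
    """Raw local-alignment score only (no traceback); used for fast screening."""
    aligner = _make_aligner(params)
    return aligner.score(query, subject)


def estimate_evalue(hit: AlignmentHit, params: ScoringParams) -> float:
    """E = m * n * 2^(-S') with m, n the effective search-space lengths."""
    if params.search_space_m <= 0 or params.search_space_n <= 0:
        raise ValueError("search space (m, n) is unset")
    return params.search_space_m * params.search_space_n * 2.0 ** (-hit.score)


def compute_h(hit: AlignmentHit, coverage_on: str = "query") -> float:
    """Homology value H = (identity/100) * min(1, aln_len / length).

    ``coverage_on`` selects whether coverage is taken over the query or the
    subject length (the upstream definition is ambiguous on this point);
    query coverage is the default.  Result is clipped to [0, 1].
    """
    length = hit.qlen if coverage_on == "query" else hit.slen
    if length <= 0:
        raise ValueError(f"{coverage_on} length is unset or zero")
    h = (hit.identity / 100.0) * min(1.0, hit.aln_len / length)
    return min(1.0, max(0.0, h))


def best_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    params: ScoringParams | None = None,
) -> dict[str, AlignmentHit]:
    """Best subject per query across a database, with E-value and H set.

    Scores all pairs (score-only pass), then runs a full traceback for the
    winning subject of each query.  Best hit = highest bit score, ties
    broken by lower E-value then lexicographic subject id -- deterministic.
    Queries with no positive-scoring alignment are absent from the result.
    """
    params = params or ScoringParams()
    m = sum(len(s) for s in queries.values())
    n = sum(len(s) for s in subjects.values())
    space = ScoringParams(
        matrix_name=params.matrix_name,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        lambda_=params.lambda_,
        K=params.K,
        search_space_m=m,
        search_space_n=n,
    )
    aligner = _make_aligner(params)
    out: dict[str, AlignmentHit] = {}
    subject_items = sorted(subjects.items())
    for qid, qseq in queries.items():
        best_sid, best_raw = None, 0.0
        for sid, sseq in subject_items:
            raw = aligner.score(qseq, sseq)
            if raw > best_raw:  # ties keep the lexicographically first subject
                best_sid, best_raw = sid, raw
        if best_sid is None:
            continue
        hit = smith_waterman(qseq, subjects[best_sid], params)
        hit.query_id = qid
        hit.subject_id = best_sid
        hit.slen = len(subjects[best_sid])
        hit.evalue = estimate_evalue(hit, space)
        hit.h_value = compute_h(hit)
        out[qid] = hit
    return out
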