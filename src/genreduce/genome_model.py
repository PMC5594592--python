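"""Domain types and readers/writers for genomes, annotations, intervals and hit tables.

Coordinates are 1-based inclusive throughout (GFF convention); the BED
convention (0-based, half-open) appears only at the output boundary in
:func:`write_bed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "Genome",
    "Interval",
    "AlignmentHit",
    "read_genome",
    "read_proteome",
    "read_hit_table",
    "write_hit_table",
    "write_annotation",
    "write_bed",
    "write_fasta",
]

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Gene:
    """One annotated gene on a chromosome.

    ``protein`` may be empty for RNA genes; otherwise it contains only the
    20 standard residues plus X.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.locus_tag}: invalid coordinates [{self.start}, {self.end}]"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.locus_tag}: strand must be + or -")
        bad = set(self.protein) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"gene {self.locus_tag}: non-standard residues {sorted(bad)}"
            )

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end, self.locus_tag)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """An annotated chromosome: a nucleotide sequence plus genes sorted by start."""

    name: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_tag in seen:
                raise ValueError(f"duplicate locus_tag {g.locus_tag}")
            seen.add(g.locus_tag)
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.locus_tag} extends past the end of {self.name} "
                    f"({g.end} > {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene(self, locus_tag: str) -> Gene:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)

    def proteome(self) -> dict[str, str]:
        """Protein sequences keyed by locus tag (protein-coding genes only)."""
        return {g.locus_tag: g.protein for g in self.genes if g.protein}

    def subsequence(self, interval: Interval) -> str:
        return self.sequence[interval.start - 1 : interval.end]


@dataclass
class AlignmentHit:
    """One protein-vs-protein comparison in BLAST tabular terms."""

    query_id: str
    subject_id: str
    identity: float  # percent over aligned columns
    aln_len: int
    qlen: int = 0
    slen: int = 0
    score: float = 0.0  # bit score
    evalue: float = float("inf")
    h_value: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.h_value is not None and not (0.0 <= self.h_value <= 1.0):
            raise ValueError("h_value outside [0, 1]")


# ---------------------------------------------------------------------------
# readers


def _translate_cds(cds: str, locus_tag: str) -> str:
    """Translate a CDS with the bacterial code (table 11).

    Alternative starts (GTG, TTG) are rendered as M; a trailing stop is
    stripped.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"gene {locus_tag}: CDS length {len(cds)} not a multiple of 3")
    aa = str(Seq(cds).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"gene {locus_tag}: internal stop codon in CDS")
    if aa:
        aa = "M" + aa[1:]
    return aa


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def _genes_from_gff3(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "CDS"):
                continue
            a = _parse_gff3_attributes(attrs)
            locus = a.get("locus_tag") or a.get("ID")
            if not locus:
                raise ValueError(f"{path}:{lineno}: feature without locus_tag/ID")
            rows.append(
                dict(
                    seqid=seqid,
                    ftype=ftype,
                    locus_tag=locus,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    product=a.get("product", ""),
                    category=a.get("category", ""),
                    protein=a.get("protein", ""),
                )
            )
    # CDS rows override/augment gene rows of the same locus
    merged: dict[str, dict] = {}
    for r in rows:
        key = r["locus_tag"]
        if key not in merged or r["ftype"] == "CDS":
            prev = merged.get(key, {})
            r = {**prev, **{k: v for k, v in r.items() if v != ""}}
            merged[key] = r
    return list(merged.values())


_TABULAR_COLUMNS = ["locus_tag", "start", "end", "strand", "product", "category"]


def _genes_from_tabular(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "locus_tag":  # header row
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated columns")
            fields += [""] * (6 - len(fields))
            rows.append(
                dict(
                    seqid=None,
                    locus_tag=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[3],
                    product=fields[4],
                    category=fields[5],
                    protein="",
                )
            )
    return rows


def _looks_like_gff3(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if line.strip() and not line.startswith("#"):
                return len(line.split("\t")) == 9
    return False


def read_genome(fasta_path: str | Path, annotation_path: str | Path) -> Genome:
    """Load a genome from a nucleotide FASTA and an annotation file.

    The annotation dialect (GFF3 vs 6-column tabular) is auto-detected.
    Proteins are taken from the annotation's ``protein`` attribute when
    present, otherwise translated from the CDS with the bacterial code.
    Multi-record FASTA is rejected here; run per contig and sum totals.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    if len(records) > 1:
        raise ValueError(
            f"{fasta_path}: {len(records)} contigs; load one contig per Genome"
        )
    rec = records[0]
    sequence = str(rec.seq).upper()

    raw = (
        _genes_from_gff3(annotation_path)
        if _looks_like_gff3(annotation_path)
        else _genes_from_tabular(annotation_path)
    )
    genes = []
    for r in raw:
        if r["end"] > len(sequence) or r["start"] < 1:
            raise ValueError(
                f"gene {r['locus_tag']} at [{r['start']}, {r['end']}] lies outside "
                f"{rec.id} (1..{len(sequence)})"
            )
        protein = r.get("protein", "")
        if not protein:
            cds = sequence[r["start"] - 1 : r["end"]]
            if r["strand"] == "-":
                cds = str(Seq(cds).reverse_complement())
            try:
                protein = _translate_cds(cds, r["locus_tag"])
            except ValueError:
                protein = ""  # RNA gene or pseudogene: no protein
        genes.append(
            Gene(
                locus_tag=r["locus_tag"],
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                product=r.get("product", ""),
                protein=protein,
                category=r.get("category", ""),
            )
        )
    return Genome(name=rec.id, sequence=sequence, genes=genes)


def read_proteome(path: str | Path) -> dict[str, str]:
    """Protein FASTA -> {id: sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def read_hit_table(
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
    subject_lengths: dict[str, int] | None = None,
) -> list[AlignmentHit]:
    """Parse a 12-column tab-delimited hit table (BLAST ``-outfmt 6`` dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Query/subject full lengths are not part
    of the format; supply them via ``seq_lengths``/``subject_lengths``
    (e.g. from the loaded proteomes) so that coverage-based scores can be
    computed later.  ``h_value`` is left unset.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                identity = float(fields[2])
                aln_len = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            qlen = 0
            if seq_lengths is not None:
                if qid not in seq_lengths:
                    raise ValueError(f"{path}:{lineno}: unknown query id {qid!r}")
                qlen = seq_lengths[qid]
            slen = (subject_lengths or {}).get(sid, 0)
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    identity=identity,
                    aln_len=aln_len,
                    qlen=qlen,
                    slen=slen,
                    score=bitscore,
                    evalue=evalue,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# writers


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Emit hits in the 12-column tab-delimited dialect (drop-in for BLAST)."""
    with open(path, "w") as fh:
        for h in hits:
            mism = max(0, round(h.aln_len * (1 - h.identity / 100)))
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity:.2f}",
                        str(h.aln_len),
                        str(mism),
                        "0",
                        "1",
                        str(h.aln_len),
                        "1",
                        str(h.aln_len),
                        f"{h.evalue:.2e}",
                        f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )


def write_annotation(genome: Genome, path: str | Path) -> None:
    """Write the 6-column tabular annotation dialect (round-trips read_genome)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABULAR_COLUMNS) + "\n")
        for g in genome.genes:
            fh.write(
                f"{g.locus_tag}\t{g.start}\t{g.end}\t{g.strand}\t{g.product}\t{g.category}\n"
            )


def write_bed(
    intervals: Sequence[Interval], path: str | Path, chrom: str = "chr"
) -> None:
    """Write intervals as BED: chromStart = start - 1, chromEnd = end."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.label or "."
            fh.write(f"{chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def write_fasta(name: str, sequence: str, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
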