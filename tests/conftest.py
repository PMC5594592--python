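import pytest

from genreduce.classify import classify_genome
from genreduce.genome_model import Gene, Genome
from genreduce.simulate import GenomeSimConfig, generate_genome_pair


def make_genome(gene_spans, length=None, seq_char="A", strands=None, categories=None):
    """Tiny genome from (locus, start, end) triples; sequence is filler."""
    genes = []
    for i, (locus, start, end) in enumerate(gene_spans):
        genes.append(
            Gene(
                locus_tag=locus,
                start=start,
                end=end,
                strand=(strands or ["+"] * len(gene_spans))[i],
                protein="M" + "A" * 10,
                category=(categories or [""] * len(gene_spans))[i],
            )
        )
    length = length or (max(e for _, _, e in gene_spans) + 500)
    return Genome(name="toy", sequence=seq_char * length, genes=genes)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_bundle():
    """Seeded synthetic genome pair: 60 genes, one planted 12-gene/16 kb run."""
    cfg = GenomeSimConfig(
        n_genes=60,
        n_essential_planted=6,
        frac_conserved=0.4,
        planted_regions=[(12, 16_000)],
        seed=1,
    )
    return generate_genome_pair(cfg)


@pytest.fixture(scope="session")
def small_classification(small_bundle):
    """Full classification of the small bundle (shared; the slow step)."""
    return classify_genome(
        small_bundle.target, small_bundle.reference_proteome, small_bundle.panels
    )
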