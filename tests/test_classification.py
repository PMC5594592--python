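import pytest

from genreduce.classify import (
    ClassificationConfig,
    STRAIN_SPECIFIC,
    subtract_genomes,
    vote_essentiality,
)
from genreduce.genome_model import AlignmentHit, Gene, Genome


def _gene(locus="G1"):
    return Gene(locus, 1, 33, "+", protein="MKLVTAHQWAA")


def _panel_hit(locus, identity=60.0, evalue=1e-20):
    return AlignmentHit(locus, "panel_prot", identity=identity, aln_len=100, qlen=100, evalue=evalue)


def _panels(n=15):
    return [{"p": "MKLVTAHQWAA"} for _ in range(n)]


class TestVoting:
    def test_eight_of_fifteen_is_essential(self):
        gene = _gene()
        hits = [
            {gene.locus_tag: _panel_hit(gene.locus_tag)} if i < 8 else {}
            for i in range(15)
        ]
        status = vote_essentiality(gene, _panels(), hits=hits)
        assert status.essential_votes == 8
        assert status.essential

    def test_seven_of_fifteen_is_not_essential(self):
        gene = _gene()
        hits = [
            {gene.locus_tag: _panel_hit(gene.locus_tag)} if i < 7 else {}
            for i in range(15)
        ]
        status = vote_essentiality(gene, _panels(), hits=hits)
        assert status.essential_votes == 7
        assert not status.essential

    def test_zero_hits_means_zero_votes(self):
        status = vote_essentiality(_gene(), _panels(), hits=[{}] * 15)
        assert status.essential_votes == 0
        assert not status.essential

    def test_thresholds_gate_the_vote(self):
        gene = _gene()
        weak_identity = [{gene.locus_tag: _panel_hit(gene.locus_tag, identity=34.9)}] * 15
        weak_evalue = [{gene.locus_tag: _panel_hit(gene.locus_tag, evalue=1e-9)}] * 15
        assert vote_essentiality(gene, _panels(), hits=weak_identity).essential_votes == 0
        assert vote_essentiality(gene, _panels(), hits=weak_evalue).essential_votes == 0
        boundary = [{gene.locus_tag: _panel_hit(gene.locus_tag, identity=35.0, evalue=1e-10)}] * 15
        assert vote_essentiality(gene, _panels(), hits=boundary).essential_votes == 15

    def test_votes_min_exceeding_panels_is_error(self):
        cfg = ClassificationConfig(essential_votes_min=8)
        with pytest.raises(ValueError, match="exceeds"):
            vote_essentiality(_gene(), _panels(5), cfg, hits=[{}] * 5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ClassificationConfig(essential_votes_min=16, panel_count=15)
        with pytest.raises(ValueError):
            ClassificationConfig(h_cutoff=0.0)


class TestSubtraction:
    def test_verbatim_copy_is_conserved_and_no_hit_is_specific(self):
        prot = "MKLVTAHQW" * 12
        other = "MWQHATVLK" * 12
        genome = Genome(
            name="t",
            sequence="A" * 1000,
            genes=[
                Gene("COPY", 1, 10, "+", protein=prot),
                Gene("NOVEL", 101, 110, "+", protein=other),
            ],
        )
        labels = subtract_genomes(genome, {"ref1": prot})
        assert labels["COPY"] == "conserved"
        assert labels["NOVEL"] == STRAIN_SPECIFIC

    def test_empty_reference_is_error(self):
        genome = Genome(name="t", sequence="A" * 100, genes=[_gene()])
        with pytest.raises(ValueError, match="empty"):
            subtract_genomes(genome, {})

    def test_precomputed_hits_respect_cutoffs(self):
        genome = Genome(
            name="t",
            sequence="A" * 1000,
            genes=[
                Gene("G1", 1, 10, "+", protein="M" + "A" * 99),
                Gene("G2", 101, 110, "+", protein="M" + "A" * 99),
            ],
        )
        hits = [
            AlignmentHit("G1", "r", identity=50.0, aln_len=100, qlen=100, evalue=1e-20),  # H=0.5
            AlignmentHit("G2", "r", identity=41.0, aln_len=100, qlen=100, evalue=1e-20),  # H=0.41
        ]
        labels = subtract_genomes(genome, {"r": "X"}, hits=hits)
        assert labels == {"G1": "conserved", "G2": STRAIN_SPECIFIC}

    def test_labels_invariant_to_gene_order(self):
        prot_a, prot_b = "MKLVTAHQW" * 10, "MWWHATPLK" * 10
        genes = [
            Gene("A", 1, 10, "+", protein=prot_a),
            Gene("B", 101, 110, "+", protein=prot_b),
        ]
        ref = {"r": prot_a}
        g1 = Genome(name="t", sequence="A" * 1000, genes=genes)
        g2 = Genome(name="t", sequence="A" * 1000, genes=list(reversed(genes)))
        assert subtract_genomes(g1, ref) == subtract_genomes(g2, ref)


class TestPlantedTruthRecovery:
    """Seeded synthetic genome pair: classification must recover the truth."""

    def test_conservation_matches_planted_truth(self, small_bundle, small_classification):
        merged = small_classification.merge(small_bundle.truth, on="locus_tag")
        predicted = merged["conservation"] == "conserved"
        assert (predicted == merged["conserved"]).all()

    def test_essentials_recovered_with_perfect_precision_recall(
        self, small_bundle, small_classification
    ):
        merged = small_classification.merge(small_bundle.truth, on="locus_tag")
        tp = (merged["essential_x"] & merged["essential_y"]).sum()
        fp = (merged["essential_x"] & ~merged["essential_y"]).sum()
        fn = (~merged["essential_x"] & merged["essential_y"]).sum()
        assert fp == 0 and fn == 0 and tp == merged["essential_y"].sum() > 0

    def test_vote_relaxation_is_monotone(self, small_classification):
        votes = small_classification["essential_votes"]
        assert (votes >= 1).sum() >= (votes >= 8).sum()
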