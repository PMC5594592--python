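import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from genreduce.constructs import (
    DesignConfig,
    RESTRICTION_SITES,
    design_arms,
    design_primers,
    melting_temp,
    simulate_overlap_pcr,
)
from genreduce.genome_model import Genome, Interval

from .conftest import random_dna


def _genome(rng, n=20_000):
    return Genome(name="toy", sequence=random_dna(rng, n), genes=[])


class TestArms:
    def test_arms_abut_deletion_endpoints(self):
        rng = np.random.default_rng(0)
        g = _genome(rng)
        arms = design_arms(g, Interval(5001, 8000))
        assert arms.upstream_interval == Interval(4401, 5000, "upstream_arm")
        assert arms.downstream_interval == Interval(8001, 8600, "downstream_arm")
        assert arms.upstream_arm == g.sequence[4400:5000]

    def test_short_flank_trims_toward_minimum(self):
        rng = np.random.default_rng(1)
        g = _genome(rng, n=10_000)
        arms = design_arms(g, Interval(451, 8000))
        assert len(arms.upstream_arm) == 450

    def test_flank_below_minimum_is_error(self):
        rng = np.random.default_rng(2)
        g = _genome(rng, n=10_000)
        with pytest.raises(ValueError, match="minimum"):
            design_arms(g, Interval(351, 8000))


class TestPrimerDesign:
    @pytest.mark.parametrize("seed", range(25))
    def test_design_properties_across_seeds(self, seed):
        rng = np.random.default_rng(seed)
        g = _genome(rng)
        start = int(rng.integers(2000, 8000))
        size = int(rng.integers(1000, 8000))
        iv = Interval(start, start + size - 1)
        arms = design_arms(g, iv)
        ps = design_primers(arms, iv, g)

        # overlap-extension PCR reassembles the exact scarless junction
        assert simulate_overlap_pcr(arms, ps) == arms.upstream_arm + arms.downstream_arm
        # overlap length bounded as specified
        assert 18 <= ps.overlap_len <= 20
        # chosen restriction sites absent from the joined insert
        insert = arms.upstream_arm + arms.downstream_arm
        for enzyme in ps.sites:
            site = RESTRICTION_SITES[enzyme]
            assert site not in insert
            assert str(Seq(site).reverse_complement()) not in insert
        assert ps.sites[0] != ps.sites[1]
        # NF/NR anneal strictly inside the deleted interval
        for p in (ps.NF, ps.NR):
            assert iv.start < p.start and p.end < iv.end
        product = ps.NR.end - ps.NF.start + 1
        assert 300 <= product <= 600
        # annealing Tm inside the window for every primer
        cfg = DesignConfig()
        for p in ps:
            anneal_sense = p.anneal if p.strand == "+" else str(Seq(p.anneal).reverse_complement())
            assert cfg.tm_min <= melting_temp(anneal_sense) <= cfg.tm_max
        # NF/NR lose their template once the deletion is applied
        reduced = g.sequence[: iv.start - 1] + g.sequence[iv.end :]
        for p in (ps.NF, ps.NR):
            probe = p.anneal if p.strand == "+" else str(Seq(p.anneal).reverse_complement())
            assert probe not in reduced

    def test_f2_tail_matches_upstream_terminus(self):
        rng = np.random.default_rng(99)
        g = _genome(rng)
        iv = Interval(6001, 9000)
        arms = design_arms(g, iv)
        ps = design_primers(arms, iv, g)
        tail = ps.F2.sequence[: ps.overlap_len]
        assert tail == arms.upstream_arm[-ps.overlap_len :]
        # and equals the reverse complement of R1's annealing 5' portion
        assert tail == str(Seq(ps.R1.sequence[: ps.overlap_len]).reverse_complement())

    def test_small_deleted_interval_rejected_for_verification(self):
        rng = np.random.default_rng(5)
        g = _genome(rng)
        iv = Interval(6001, 6200)  # 200 bp < 300 bp verification floor
        arms = design_arms(g, iv)
        with pytest.raises(ValueError, match="too small"):
            design_primers(arms, iv, g)


class TestMeltingTemp:
    def test_gc_raises_tm(self):
        assert melting_temp("A" * 20 + "T" * 20) < melting_temp("G" * 20 + "C" * 20)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = random_dna(rng, 22)
            rc = str(Seq(seq).reverse_complement())
            assert melting_temp(seq) == pytest.approx(melting_temp(rc), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_nearest_neighbor_summation(self, seed):
        """Cross-check against an independent NN implementation.

        Same physical convention: unified parameters, 50 mM Na+, effective
        duplex concentration CT/4 = 125 nM, entropy salt correction.
        """
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 20)
        ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=125, dnac2=0, saltcorr=5)
        assert melting_temp(seq) == pytest.approx(ref, abs=0.05)

    def test_wallace_rule_for_short_sequences(self):
        assert melting_temp("ATGCATGCAT") == 2 * 6 + 4 * 4

    def test_errors(self):
        with pytest.raises(ValueError, match="short"):
            melting_temp("ATGC")
        with pytest.raises(ValueError, match="ambiguous"):
            melting_temp("ATGCNATGCATGCA")
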