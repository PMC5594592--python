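import pandas as pd
import pytest

from genreduce.regions import (
    RegionCandidate,
    RegionCriteria,
    filter_regions,
    find_candidate_runs,
    order_plan,
    snap_endpoints,
)
from genreduce.genome_model import Interval

from .conftest import make_genome
from .oracles import enumerate_qualifying_runs


def _statuses(loci, pattern):
    """pattern: S=specific, C=conserved, E=essential (conserved)."""
    rows = []
    for locus, p in zip(loci, pattern):
        rows.append(
            dict(
                locus_tag=locus,
                conservation="strain_specific" if p == "S" else "conserved",
                essential=(p == "E"),
            )
        )
    return pd.DataFrame(rows)


def _spaced_genome(n, gene_len=300, gap=100):
    spans = []
    pos = 1000
    for i in range(n):
        spans.append((f"G{i+1}", pos, pos + gene_len - 1))
        pos += gene_len + gap
    return make_genome(spans, length=pos + 2000)


class TestRuns:
    def test_conserved_gene_splits_runs(self):
        g = _spaced_genome(6)
        runs = find_candidate_runs(_statuses([x.locus_tag for x in g.genes], "SSSCSS"), g)
        assert [len(r) for r in runs] == [3, 2]

    def test_essential_gene_splits_runs(self):
        g = _spaced_genome(7)
        runs = find_candidate_runs(_statuses([x.locus_tag for x in g.genes], "SSSESSS"), g)
        assert [len(r) for r in runs] == [3, 3]

    def test_planted_run_found_exactly(self, small_bundle, small_classification):
        runs = find_candidate_runs(small_classification, small_bundle.target)
        planted = set(
            small_bundle.truth.loc[small_bundle.truth["region"] == "R1", "locus_tag"]
        )
        exact = [r for r in runs if {g.locus_tag for g in r} == planted]
        assert len(exact) == 1 and len(exact[0]) == 12

    def test_matches_brute_force_enumerator(self, small_bundle, small_classification):
        runs = find_candidate_runs(small_classification, small_bundle.target)
        mine = [[g.locus_tag for g in r] for r in runs if len(r) >= 11]
        oracle = enumerate_qualifying_runs(
            small_bundle.target, small_classification, 11
        )
        assert mine == oracle


class TestSnapping:
    def test_midpoint_of_intergenic_gap(self):
        g = make_genome([("N1", 500, 1000), ("R1", 1101, 1400), ("N2", 1501, 1900)])
        iv = snap_endpoints([g.genes[1]], g)
        assert iv.start == 1050  # midpoint of the 100 bp gap
        assert iv.end == 1450

    def test_overlapping_neighbor_retracts_inside_region(self):
        # neighbor overlaps the run's first gene by 30 bp
        g = make_genome([("N1", 500, 1130), ("R1", 1101, 1400), ("N2", 1501, 1900)])
        iv = snap_endpoints([g.genes[1]], g)
        assert iv.start == 1101 + 30

    def test_genome_edges(self):
        g = make_genome([("R1", 101, 400)], length=1000)
        iv = snap_endpoints([g.genes[0]], g)
        assert (iv.start, iv.end) == (1, 1000)


class TestFiltering:
    def _run_of(self, n, gene_len, gap):
        g = _spaced_genome(n + 2, gene_len=gene_len, gap=gap)
        statuses = _statuses([x.locus_tag for x in g.genes], "C" + "S" * n + "C")
        runs = find_candidate_runs(statuses, g)
        return g, statuses, runs

    def test_span_boundary(self):
        # 12 genes x 1300 bp + 11 gaps x 100 bp = 16,700 bp gene span
        g, statuses, runs = self._run_of(12, 1300, 100)
        accepted = filter_regions(runs, RegionCriteria(), g, statuses=statuses)
        assert len(accepted) == 1 and accepted[0].gene_count == 12
        # same layout but too short overall -> rejected (snapped span < 15 kb)
        g2, s2, runs2 = self._run_of(12, 1000, 60)
        assert filter_regions(runs2, RegionCriteria(), g2, statuses=s2) == []

    def test_gene_count_boundary(self):
        g, statuses, runs = self._run_of(10, 2000, 100)  # 10 genes, >15 kb
        assert filter_regions(runs, RegionCriteria(), g, statuses=statuses) == []
        g2, s2, runs2 = self._run_of(11, 2000, 100)
        assert len(filter_regions(runs2, RegionCriteria(), g2, statuses=s2)) == 1

    def test_curated_cluster_bypasses_size_filters(self):
        g = _spaced_genome(4)
        statuses = _statuses([x.locus_tag for x in g.genes], "CSSC")
        accepted = filter_regions(
            [], RegionCriteria(), g, clusters=[("hcn", "G2", "G3")], statuses=statuses
        )
        assert len(accepted) == 1
        assert accepted[0].priority_class == "secondary_metabolite_cluster"
        assert accepted[0].span_bp < 15_000

    def test_curated_cluster_over_essential_gene_is_error(self):
        g = _spaced_genome(4)
        statuses = _statuses([x.locus_tag for x in g.genes], "CSEC")
        with pytest.raises(ValueError, match="G3"):
            filter_regions(
                [], RegionCriteria(), g, clusters=[("bad", "G2", "G3")], statuses=statuses
            )

    def test_monotone_in_criteria(self, small_bundle, small_classification):
        runs = find_candidate_runs(small_classification, small_bundle.target)
        g = small_bundle.target
        s = small_classification
        loose = filter_regions(runs, RegionCriteria(min_span_bp=1000, min_gene_run=2), g, statuses=s)
        strict = filter_regions(runs, RegionCriteria(), g, statuses=s)
        assert len(strict) <= len(loose)

    def test_no_candidate_touches_an_essential_gene(
        self, small_bundle, small_classification
    ):
        runs = find_candidate_runs(small_classification, small_bundle.target)
        cands = filter_regions(
            runs,
            RegionCriteria(min_span_bp=1000, min_gene_run=2),
            small_bundle.target,
            statuses=small_classification,
        )
        essential = small_classification.loc[
            small_classification["essential"], "locus_tag"
        ]
        ess_ivs = [small_bundle.target.gene(l).interval for l in essential]
        for c in cands:
            for iv in ess_ivs:
                assert not c.interval.overlaps(iv)


class TestOrdering:
    def _cand(self, start, cls):
        return RegionCandidate(
            genes=["x"], interval=Interval(start, start + 99), priority_class=cls
        )

    def test_priority_class_order_then_position(self):
        cands = [
            self._cand(5000, "hypothetical"),
            self._cand(1000, "metabolism_transport"),
            self._cand(9000, "secondary_metabolite_cluster"),
            self._cand(3000, "secondary_metabolite_cluster"),
        ]
        plan = order_plan(cands, 100_000)
        assert [r.priority_class for r in plan.regions] == [
            "secondary_metabolite_cluster",
            "secondary_metabolite_cluster",
            "metabolism_transport",
            "hypothetical",
        ]
        assert [r.interval.start for r in plan.regions] == [3000, 9000, 1000, 5000]
        assert [r.name for r in plan.regions] == ["MD1", "MD2", "MD3", "MD4"]

    def test_same_class_sorts_by_position(self):
        cands = [self._cand(p, "hypothetical") for p in (7000, 1000, 4000)]
        plan = order_plan(cands, 100_000)
        assert [r.interval.start for r in plan.regions] == [1000, 4000, 7000]

    def test_overlapping_plan_rejected(self):
        cands = [self._cand(1000, "hypothetical"), self._cand(1050, "hypothetical")]
        with pytest.raises(ValueError, match="overlap"):
            order_plan(cands, 100_000)
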