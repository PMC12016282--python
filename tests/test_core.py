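from __future__ import annotations

from fractions import Fraction

import pytest

from brackenlite.core import (
    EstimationConfig,
    KrakenReport,
    NoSignalError,
    SpeciesEstimate,
    allocate_node_reads,
    compute_priors,
    detect_taxa,
    estimate_abundance,
    estimate_at_level,
    estimate_derived_total,
)
from brackenlite.distribution import GenomeDistribution, KmerDistribution

from conftest import build_tree


def make_dist(per, *, r=75, k=31):
    """per: taxid -> (num_windows, node_counts)."""
    return KmerDistribution(
        read_length=r,
        k=k,
        per_genome={
            t: GenomeDistribution(taxid=t, num_windows=n, node_counts=c)
            for t, (n, c) in per.items()
        },
    )


@pytest.fixture(scope="module")
def two_species_tree():
    return build_tree(
        [
            (1, 1, "root", "root"),
            (2, 1, "genus", "G"),
            (3, 2, "species", "S1"),
            (4, 2, "species", "S2"),
        ]
    )


@pytest.fixture(scope="module")
def two_species_dist():
    # S1: half its windows are genus-ambiguous (U=1/2); S2 mostly unique (U=9/10)
    return make_dist({3: (10, {3: 5, 2: 5}), 4: (10, {4: 9, 2: 1})})


class TestDerivedTotal:
    def test_quarter_unique_quadruples(self):
        assert estimate_derived_total(1000, Fraction(1, 4)) == 4000

    def test_fully_unique_is_identity(self):
        assert estimate_derived_total(123, Fraction(1)) == 123

    def test_degenerate_unique_fractions_rejected(self):
        with pytest.raises(ValueError):
            estimate_derived_total(10, 0)
        with pytest.raises(ValueError):
            estimate_derived_total(10, Fraction(11, 10))


class TestPriorsAndAllocation:
    def test_priors_normalise_derived_totals(self):
        ests = [
            SpeciesEstimate(3, Fraction(1000), Fraction(1, 2), Fraction(2000)),
            SpeciesEstimate(4, Fraction(450), Fraction(9, 10), Fraction(500)),
        ]
        compute_priors(ests)
        assert ests[0].prior == Fraction(4, 5)
        assert ests[1].prior == Fraction(1, 5)

    def test_all_zero_signal_raises(self):
        ests = [SpeciesEstimate(3, Fraction(0), Fraction(1, 2), Fraction(0))]
        with pytest.raises(NoSignalError):
            compute_priors(ests)
        with pytest.raises(ValueError):
            compute_priors([])

    def test_genus_reads_split_by_bayes_scores(self):
        # scores: (1/2)(4/5)=2/5 and (1/10)(1/5)=1/50 -> shares 20/21, 1/21
        alloc = allocate_node_reads(
            2,
            420,
            [
                (3, Fraction(1, 2), Fraction(4, 5)),
                (4, Fraction(1, 10), Fraction(1, 5)),
            ],
        )
        assert alloc.shares == {3: Fraction(20, 21), 4: Fraction(1, 21)}
        assert alloc.allocated == {3: Fraction(400), 4: Fraction(20)}

    def test_allocation_conserves_reads_exactly(self):
        alloc = allocate_node_reads(
            2,
            17,
            [
                (3, Fraction(1, 3), Fraction(1, 7)),
                (4, Fraction(2, 5), Fraction(6, 7)),
            ],
        )
        assert sum(alloc.allocated.values(), Fraction(0)) == 17

    def test_zero_scores_leave_reads_unallocated(self):
        alloc = allocate_node_reads(2, 50, [(3, Fraction(0), Fraction(1))])
        assert alloc.allocated == {}
        assert allocate_node_reads(2, 50, []).allocated == {}


class TestKrakenReport:
    def test_clade_counts_from_direct(self, two_species_tree):
        rep = KrakenReport.from_direct_counts(
            {3: 7, 4: 5, 2: 2}, two_species_tree, unclassified=3
        )
        assert rep.clade(2) == 14
        assert rep.clade(1) == 14
        assert rep.direct(2) == 2
        assert rep.classified_reads == 14
        assert rep.total_reads == 17
        rep.validate(two_species_tree)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            KrakenReport({3: -1}, {3: -1})
        with pytest.raises(ValueError):
            KrakenReport({0: 5}, {0: 5})


class TestDetection:
    def test_threshold_applies_to_rolled_up_counts(self, myco_tree):
        # 4 species reads + 7 strain reads roll up to 11 >= 10
        rep = KrakenReport.from_direct_counts({5: 4, 51: 7, 6: 9}, myco_tree)
        cfg = EstimationConfig(threshold=10)
        assert detect_taxa(rep, cfg, myco_tree) == {5}

    def test_threshold_zero_still_requires_one_read(self, myco_tree):
        rep = KrakenReport.from_direct_counts({5: 1}, myco_tree)
        cfg = EstimationConfig(threshold=0)
        assert detect_taxa(rep, cfg, myco_tree) == {5}

    def test_reads_above_level_do_not_create_candidates(self, myco_tree):
        rep = KrakenReport.from_direct_counts({3: 100}, myco_tree)
        cfg = EstimationConfig(threshold=1)
        assert detect_taxa(rep, cfg, myco_tree) == set()


class TestEstimateAbundance:
    def test_worked_two_species_case(self, two_species_tree, two_species_dist):
        rep = KrakenReport.from_direct_counts({3: 1000, 4: 450, 2: 420}, two_species_tree)
        table = estimate_abundance(rep, two_species_dist, two_species_tree)
        assert table.row(3).new_est_reads == 1400
        assert table.row(4).new_est_reads == 470
        assert table.row(3).added_reads == 400
        assert table.row(4).added_reads == 20
        assert table.unallocated_reads == 0
        assert table.row(3).fraction_total_reads == Fraction(1400, 1870)
        # rows sorted by estimate, descending
        assert [r.taxid for r in table.rows] == [3, 4]

    def test_identity_limit_fully_unique_genomes(self, two_species_tree):
        # no shared windows and no stranded reads: the estimator is a no-op
        dist = make_dist({3: (10, {3: 10}), 4: (10, {4: 10})})
        rep = KrakenReport.from_direct_counts({3: 321, 4: 123}, two_species_tree)
        table = estimate_abundance(rep, dist, two_species_tree)
        assert table.row(3).new_est_reads == 321
        assert table.row(4).new_est_reads == 123
        assert table.unallocated_reads == 0

    def test_exact_read_conservation(self, two_species_tree, two_species_dist):
        rep = KrakenReport.from_direct_counts(
            {3: 13, 4: 17, 2: 19, 1: 23}, two_species_tree, unclassified=5
        )
        # root reads cannot be placed (no genome shows the root), which must
        # be reported loudly and land in the unallocated pool
        with pytest.warns(RuntimeWarning, match="unallocated"):
            table = estimate_abundance(
                rep, two_species_dist, two_species_tree, EstimationConfig(threshold=1)
            )
        placed = sum((r.new_est_reads for r in table.rows), Fraction(0))
        assert placed + table.unallocated_reads == rep.classified_reads
        # per-node conservation: each allocation sums to its node's reads
        for alloc in table.allocations:
            if alloc.allocated:
                assert sum(alloc.allocated.values(), Fraction(0)) == alloc.node_reads

    def test_scale_equivariance(self, two_species_tree, two_species_dist):
        direct = {3: 40, 4: 50, 2: 21}
        cfg = EstimationConfig(threshold=0)
        t1 = estimate_abundance(
            KrakenReport.from_direct_counts(direct, two_species_tree),
            two_species_dist,
            two_species_tree,
            cfg,
        )
        t7 = estimate_abundance(
            KrakenReport.from_direct_counts(
                {t: 7 * c for t, c in direct.items()}, two_species_tree
            ),
            two_species_dist,
            two_species_tree,
            cfg,
        )
        for r in t1.rows:
            assert t7.row(r.taxid).new_est_reads == 7 * r.new_est_reads
        assert t7.unallocated_reads == 7 * t1.unallocated_reads

    def test_strain_reads_roll_up_to_species(self, myco_tree):
        dist = make_dist({51: (10, {51: 10}), 52: (10, {52: 10})})
        rep = KrakenReport.from_direct_counts({51: 30, 52: 20, 5: 5}, myco_tree)
        table = estimate_abundance(rep, dist, myco_tree)
        assert table.row(5).kraken_assigned_reads == 55
        assert table.row(5).new_est_reads == 55
        assert len(table.rows) == 1

    def test_undetected_species_reads_go_unallocated(self, two_species_tree, two_species_dist):
        rep = KrakenReport.from_direct_counts({3: 100, 4: 4}, two_species_tree)
        table = estimate_abundance(rep, two_species_dist, two_species_tree)
        assert [r.taxid for r in table.rows] == [3]
        assert table.unallocated_reads == 4

    def test_subtree_without_genomes_goes_unallocated(self, myco_tree):
        dist = make_dist({51: (10, {51: 10})})
        # genus_h (8) has reads but no genome anywhere below it
        rep = KrakenReport.from_direct_counts({51: 100, 8: 40}, myco_tree)
        table = estimate_abundance(rep, dist, myco_tree)
        assert table.unallocated_reads == 40
        assert table.row(5).new_est_reads == 100

    def test_genus_only_candidates_get_everything(self, two_species_tree, two_species_dist):
        # S2 undetected: genus reads all flow to S1 regardless of its share
        rep = KrakenReport.from_direct_counts({3: 100, 2: 60}, two_species_tree)
        table = estimate_abundance(rep, two_species_dist, two_species_tree)
        assert table.row(3).new_est_reads == 160

    def test_zero_unique_fraction_warns_and_keeps_kraken_count(self, two_species_tree):
        dist = make_dist({3: (10, {2: 10}), 4: (10, {4: 10})})
        rep = KrakenReport.from_direct_counts({3: 50, 4: 50}, two_species_tree)
        with pytest.warns(RuntimeWarning, match="unique"):
            table = estimate_abundance(rep, dist, two_species_tree)
        assert table.row(3).new_est_reads == 50

    def test_detected_taxon_without_genome_warns(self, two_species_tree, two_species_dist):
        dist = make_dist({3: (10, {3: 5, 2: 5})})
        rep = KrakenReport.from_direct_counts({3: 100, 4: 100}, two_species_tree)
        with pytest.warns(RuntimeWarning, match="4"):
            estimate_abundance(rep, dist, two_species_tree)

    def test_read_length_mismatch_warns(self, two_species_tree, two_species_dist):
        rep = KrakenReport.from_direct_counts({3: 100}, two_species_tree)
        with pytest.warns(RuntimeWarning, match="read length"):
            estimate_abundance(
                rep,
                two_species_dist,
                two_species_tree,
                EstimationConfig(read_length=100),
            )


@pytest.fixture(scope="module")
def two_genus_setup():
    tree = build_tree(
        [
            (1, 1, "root", "root"),
            (2, 1, "genus", "GA"),
            (3, 1, "genus", "GB"),
            (4, 2, "species", "A1"),
            (5, 2, "species", "A2"),
            (6, 3, "species", "B1"),
        ]
    )
    dist = make_dist(
        {4: (10, {4: 8, 1: 2}), 5: (10, {5: 8, 1: 2}), 6: (10, {6: 8, 1: 2})}
    )
    rep = KrakenReport.from_direct_counts({4: 100, 5: 50, 6: 30, 1: 20}, tree)
    return tree, dist, rep


class TestEstimateAtLevel:
    def test_root_level_collects_everything(self, two_genus_setup):
        tree, dist, rep = two_genus_setup
        table = estimate_at_level(rep, dist, tree, "root", threshold=1)
        assert len(table.rows) == 1
        assert table.rows[0].new_est_reads == rep.classified_reads

    def test_genus_table_sums_species_table(self, two_genus_setup):
        # with reads only at species leaves and the root, per-genome
        # allocations are level-independent, so the two tables must agree
        tree, dist, rep = two_genus_setup
        species = estimate_at_level(rep, dist, tree, "species", threshold=1)
        genus = estimate_at_level(rep, dist, tree, "genus", threshold=1)
        assert genus.row(2).new_est_reads == (
            species.row(4).new_est_reads + species.row(5).new_est_reads
        )
        assert genus.row(3).new_est_reads == species.row(6).new_est_reads
        assert genus.unallocated_reads == species.unallocated_reads == 0

    def test_root_reads_split_by_priors_when_shares_equal(self, two_genus_setup):
        # all genomes show the root the same fraction (2/10), so the Bayes
        # split reduces to the priors, i.e. proportional to K/U
        tree, dist, rep = two_genus_setup
        table = estimate_at_level(rep, dist, tree, "species", threshold=1)
        assert table.row(4).added_reads == Fraction(20 * 100, 180)
        assert table.row(5).added_reads == Fraction(20 * 50, 180)
        assert table.row(6).added_reads == Fraction(20 * 30, 180)


def test_config_validation():
    with pytest.raises(ValueError):
        EstimationConfig(level="variety")
    with pytest.raises(ValueError):
        EstimationConfig(threshold=-1)
    with pytest.raises(ValueError):
        EstimationConfig(read_length=0)
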