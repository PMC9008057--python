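"""Topology classification, minor-topology tests and the ILS null."""

import math

import dendropy
import numpy as np
import pytest
from scipy.stats import binom

from hhscan.io import GroupMap, InputError
from hhscan.network import ParameterError, SampleDesign, SpeciesNetwork
from hhscan.simulate import design_group_map, simulate_gene_trees
from hhscan.stats import UndefinedResult
from hhscan.topology import (
    TopologyCounts,
    calibrate_internal_branch,
    census,
    classify_all,
    classify_topology,
    ils_null_ratio_test,
    minor_topology_binomial_test,
    null_network_from_counts,
    windowed_distribution,
)
from hhscan.trees import GeneTreeSet


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="default-rooted",
        preserve_underscores=True,
    )


class TestClassifyTopology:
    @pytest.mark.parametrize(
        "newick, label",
        [
            ("(((C1,D1)100,O1)100,A1);", "I"),
            ("(((D1,O1)90,C1)90,A1);", "II"),
            ("(((C1,O1)80,D1)80,A1);", "III"),
            ("(((C1,O1)40,D1)90,A1);", "discarded"),  # pair support below 50
            ("((C1,D1,O1),A1);", "discarded"),  # unresolved ingroup polytomy
        ],
    )
    def test_single_tip_examples(self, newick, label, single_tip_groups):
        assert classify_topology(_tree(newick), single_tip_groups) == label

    def test_support_exactly_at_threshold_kept(self, single_tip_groups):
        assert classify_topology(_tree("(((C1,D1)50,O1),A1);"), single_tip_groups) == "I"

    def test_no_support_label_means_no_filter(self, single_tip_groups):
        assert classify_topology(_tree("(((C1,D1),O1),A1);"), single_tip_groups) == "I"

    def test_missing_group_is_an_error(self, single_tip_groups):
        with pytest.raises(InputError, match="O"):
            classify_topology(_tree("((C1,D1),A1);"), single_tip_groups)

    def test_multitip_monophyly_required(self):
        groups = GroupMap(
            {"C1": "C", "C2": "C", "D1": "D", "D2": "D", "O1": "O", "A1": "A"}
        )
        good = _tree("((((C1,C2),(D1,D2)),O1),A1);")
        assert classify_topology(good, groups) == "I"
        # one C tip nested inside the D clade: C is non-monophyletic
        bad = _tree("((((C1,(D1,C2)),D2),O1),A1);")
        assert classify_topology(bad, groups) == "discarded"

    def test_invariant_to_rotation_and_outgroup_rooting(self, single_tip_groups):
        # same unrooted tree written three ways, rooted on or around A
        forms = [
            "(((D1,C1),O1),A1);",
            "(A1,(O1,(C1,D1)));",
            "((O1,(C1,D1)),A1);",
        ]
        labels = {classify_topology(_tree(f), single_tip_groups) for f in forms}
        assert labels == {"I"}


class TestCensus:
    def test_mixed_fixture_matches_hand_count(self, single_tip_groups):
        """Twelve-tree fixture whose labels were assigned by hand."""
        newicks = (
            ["(((C1,D1)99,O1)99,A1);"] * 5  # I
            + ["(((D1,O1)88,C1)88,A1);"] * 3  # II
            + ["(((C1,O1)77,D1)77,A1);"] * 2  # III
            + ["(((C1,D1)30,O1)95,A1);"] * 2  # discarded (low support)
        )
        trees = GeneTreeSet(trees=[_tree(n) for n in newicks])
        counts = census(trees, single_tip_groups)
        assert (counts.n_I, counts.n_II, counts.n_III, counts.n_discarded) == (5, 3, 2, 2)
        assert counts.total_classified == 10

    def test_order_invariance(self, single_tip_groups):
        newicks = [
            "(((C1,D1),O1),A1);",
            "(((D1,O1),C1),A1);",
            "(((C1,O1),D1),A1);",
        ] * 3
        fwd = census(GeneTreeSet(trees=[_tree(n) for n in newicks]), single_tip_groups)
        rev = census(
            GeneTreeSet(trees=[_tree(n) for n in newicks[::-1]]), single_tip_groups
        )
        assert fwd == rev

    def test_all_topology_one(self, single_tip_groups):
        trees = GeneTreeSet(trees=[_tree("(((C1,D1),O1),A1);")] * 10)
        counts = census(trees, single_tip_groups)
        assert (counts.n_I, counts.n_II, counts.n_III) == (10, 0, 0)


class TestBinomialTest:
    def test_symmetric_counts_give_p_one(self):
        p = minor_topology_binomial_test(TopologyCounts(0, 10, 10))
        assert p == pytest.approx(1.0)

    def test_one_sided_extreme_closed_form(self):
        p = minor_topology_binomial_test(TopologyCounts(0, 10, 0))
        assert p == pytest.approx(2 * 0.5**10)

    @pytest.mark.parametrize("n2, n3", [(30, 12), (7, 3), (0, 5), (13, 13)])
    def test_matches_bruteforce_enumeration(self, n2, n3):
        """Two-tailed mass = sum of outcome probabilities <= P(observed)."""
        n = n2 + n3
        p_obs = binom.pmf(n2, n, 0.5)
        expected = sum(
            binom.pmf(k, n, 0.5) for k in range(n + 1) if binom.pmf(k, n, 0.5) <= p_obs * (1 + 1e-10)
        )
        assert minor_topology_binomial_test(TopologyCounts(0, n2, n3)) == pytest.approx(
            expected
        )

    def test_all_small_n_match_enumeration(self):
        for n in range(1, 21):
            for k in range(n + 1):
                p_obs = binom.pmf(k, n, 0.5)
                expected = sum(
                    binom.pmf(j, n, 0.5)
                    for j in range(n + 1)
                    if binom.pmf(j, n, 0.5) <= p_obs * (1 + 1e-10)
                )
                got = minor_topology_binomial_test(TopologyCounts(0, k, n - k))
                assert got == pytest.approx(expected), (n, k)

    def test_empty_minor_classes_undefined(self):
        with pytest.raises(UndefinedResult):
            minor_topology_binomial_test(TopologyCounts(5, 0, 0))


class TestIlsNull:
    def test_calibration_recovers_internal_branch(self):
        # P(I) = 1 - (2/3) e^{-T} inverted exactly
        T = 0.8
        p1 = 1 - (2 / 3) * math.exp(-T)
        # large classified total so the observed fraction is nearly exact
        n1 = int(round(p1 * 1_000_000))
        counts = TopologyCounts(n1, (1_000_000 - n1) // 2, (1_000_000 - n1) // 2)
        assert calibrate_internal_branch(counts) == pytest.approx(T, abs=1e-4)

    def test_calibration_needs_concordance_excess(self):
        with pytest.raises(ParameterError):
            calibrate_internal_branch(TopologyCounts(100, 200, 200))

    def test_median_ratio_gives_p_near_one(self):
        net = SpeciesNetwork(t_h=5.0, t_co=6.0, t_root=9.0, gamma=0.0)
        counts = TopologyCounts(7547, 1227, 1226)  # r_obs ~ 1, the null median
        res = ils_null_ratio_test(counts, net, loci_per_rep=10_000, n_reps=2000, seed=1)
        assert res.p_empirical > 0.5

    def test_replicate_ratio_centred_on_one_under_symmetry(self):
        net = SpeciesNetwork(t_h=5.0, t_co=6.0, t_root=9.0, gamma=0.0)
        counts = TopologyCounts(7547, 1227, 1226)
        res = ils_null_ratio_test(counts, net, loci_per_rep=4769, n_reps=3000, seed=2)
        se = res.replicate_ratios.std() / math.sqrt(res.n_reps)
        assert abs(res.replicate_ratios.mean() - 1.0) < 3 * se + 0.01

    def test_depressed_observed_ratio_rejected(self):
        """An observed III/II ratio like the study's (906/1449) is far outside
        an ILS-only null calibrated to the observed concordance level."""
        counts = TopologyCounts(2414, 1449, 906)
        net = null_network_from_counts(counts)
        res = ils_null_ratio_test(counts, net, n_reps=2000, seed=3)
        assert res.r_obs == pytest.approx(906 / 1449)
        assert res.p_empirical <= 1 / 1000  # floored at 1/n_reps
        assert res.p_t < 1e-10

    def test_genealogy_method_agrees(self):
        net = SpeciesNetwork(t_h=5.0, t_co=6.0, t_root=9.0, gamma=0.0)
        counts = TopologyCounts(2414, 1449, 906)
        res = ils_null_ratio_test(
            counts, net, loci_per_rep=500, n_reps=60, seed=4, method="genealogy"
        )
        assert res.p_empirical <= 2 / 60

    def test_gamma_network_rejected(self):
        with pytest.raises(ParameterError):
            ils_null_ratio_test(
                TopologyCounts(10, 5, 5), SpeciesNetwork(gamma=0.1), n_reps=10, seed=5
            )


class TestWindowedDistribution:
    def test_single_window_degenerate(self):
        anchors = [("chr1", 100), ("chr1", 200)]
        table, p = windowed_distribution(anchors, ["I", "II"], window_size=1_000_000)
        assert len(table) == 1
        assert math.isnan(p)

    def test_forced_cluster_detected(self):
        anchors = [("chr1", 1 + i * 1_000_000) for i in range(10) for _ in range(40)]
        labels = []
        for w in range(10):
            labels.extend(["II"] * 40 if w == 0 else ["I"] * 30 + ["II"] * 10)
        table, p = windowed_distribution(anchors, labels, window_size=1_000_000)
        assert len(table) == 10
        assert p < 1e-6

    def test_uniform_labels_calibrated(self):
        """Random label placement rarely triggers the homogeneity test."""
        rng = np.random.default_rng(6)
        n_sig = 0
        n_seeds = 60
        for _ in range(n_seeds):
            anchors = [
                ("chr1", 1 + int(w) * 1_000_000) for w in rng.integers(0, 10, size=400)
            ]
            labels = np.where(rng.random(400) < 0.4, "II", "I").tolist()
            _, p = windowed_distribution(anchors, labels, window_size=1_000_000)
            n_sig += p < 0.01
        assert n_sig <= math.ceil(0.05 * n_seeds)

    def test_requires_anchors(self):
        with pytest.raises(InputError):
            windowed_distribution(None, ["I"])

    def test_end_to_end_with_simulated_anchors(self, small_design):
        net = SpeciesNetwork(t_h=2.0, t_co=2.5, t_root=5.0, gamma=0.11)
        trees = simulate_gene_trees(net, small_design, 60, seed=7)
        groups = design_group_map(small_design)
        labels = classify_all(trees, groups)
        table, _ = windowed_distribution(trees.anchors, labels, window_size=10_000_000)
        assert table["n_I"].sum() == labels.count("I")
        assert table["n_II"].sum() == labels.count("II")
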