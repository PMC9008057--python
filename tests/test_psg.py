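"""Positive-selection scan: S/K counting, HKA, N_fix, origin, calls."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from hhscan.io import GroupMap, InputError, alignment_from_strings
from hhscan.network import ParameterError
from hhscan.psg import (
    alternating_fixed_aa,
    assign_origin,
    call_hybrid_signal,
    count_fixed_nonsynonymous,
    gene_stats,
    hka_test,
    polymorphism_divergence,
    rank_top_fraction,
    scan_genes,
)

GROUPS_2EACH = GroupMap(
    {"C1": "C", "C2": "C", "D1": "D", "D2": "D", "O1": "O", "O2": "O", "A1": "A"}
)


def _aln(seqs: dict, gene_id: str = "g"):
    return alignment_from_strings(gene_id, list(seqs.items()))


class TestPolymorphismDivergence:
    def test_identical_sequences(self):
        aln = _aln({n: "ATGATG" for n in ("C1_1", "D1_1", "O1_1")})
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert polymorphism_divergence(aln, groups, "DC_vs_O")[:2] == (0, 0)

    def test_single_fixed_difference(self):
        aln = _aln({"C1_1": "ATG", "D1_1": "ATG", "O1_1": "CTG"})
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert polymorphism_divergence(aln, groups, "DC_vs_O")[:2] == (0, 1)

    def test_twelve_column_toy_matches_hand_count(self):
        """Columns enumerated by hand:
        1 invariant, 2 S (polymorphic within D+C), 3 K (fixed different),
        1 shared-polymorphism column (neither S... actually S), 1 gap column
        excluded, rest invariant."""
        #            123456789012
        seqs = {
            "C1_1": "AAGTACGTACGT",
            "C2_1": "AAGTACGTACGT",
            "D1_1": "ACGTACGTACGT",  # col 2: S (poly within DC)
            "D2_1": "AAGTACGTACGT",
            "O1_1": "AAGAAAGTACGT",  # col 4,6: candidate K columns
            "O2_1": "AAGAAAGT-CGT",  # col 9 gap: excluded
        }
        aln = _aln(seqs)
        groups = GroupMap({"C1": "C", "C2": "C", "D1": "D", "D2": "D", "O1": "O", "O2": "O"})
        s, k, excl = polymorphism_divergence(aln, groups, "DC_vs_O")
        # hand count: col2 S; col4 fixed T|A -> K; col6 fixed C|A -> K; col9 excluded
        assert (s, k, excl) == (1, 2, 1)

    def test_empty_side_rejected(self):
        aln = _aln({"C1_1": "ATG", "D1_1": "ATG"})
        groups = GroupMap({"C1": "C", "D1": "D"})
        with pytest.raises(InputError):
            polymorphism_divergence(aln, groups, "DC_vs_O")


class TestHka:
    def test_equal_proportions_give_unity_p(self):
        chi2, p = hka_test(10, 20, 100, 200)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_toy_table_matches_closed_form(self):
        S_g, K_g, S_tot, K_tot = 5, 20, 1000, 2000
        a, b = S_g, K_g
        c, d = S_tot - S_g, K_tot - K_g
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, p = hka_test(S_g, K_g, S_tot, K_tot)
        assert chi2 == pytest.approx(expected)
        ref = chi2_contingency(np.array([[a, b], [c, d]]), correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_gene_exceeding_genome_rejected(self):
        with pytest.raises(ParameterError):
            hka_test(50, 1, 20, 100)

    def test_zero_margin_nan(self):
        chi2, p = hka_test(0, 0, 0, 10)
        assert math.isnan(chi2) and math.isnan(p)


class TestFixedNonsynonymous:
    def test_synonymous_fixed_difference_not_counted(self):
        aln = _aln({"C1_1": "GAA", "D1_1": "GAA", "O1_1": "GAG"})  # Glu vs Glu
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert count_fixed_nonsynonymous(aln, groups, "DC_vs_O") == 0

    def test_nonsynonymous_fixed_difference_counted(self):
        aln = _aln({"C1_1": "GAA", "D1_1": "GAA", "O1_1": "GAT"})  # Glu vs Asp
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert count_fixed_nonsynonymous(aln, groups, "DC_vs_O") == 1

    def test_five_codon_toy_matches_hand_translation(self):
        # codons: AAA/AAA (Lys=Lys), GAA/GAT (Glu!=Asp), ATG/ATG, CGT/CAT
        # (Arg!=His), TTA/TTG (Leu=Leu) -> 2 replacements
        aln = _aln(
            {
                "C1_1": "AAAGAAATGCGTTTA",
                "D1_1": "AAAGAAATGCGTTTA",
                "O1_1": "AAAGATATGCATTTG",
            }
        )
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert count_fixed_nonsynonymous(aln, groups, "DC_vs_O") == 2

    def test_ambiguous_codons_skipped(self):
        aln = _aln({"C1_1": "GAANNN", "D1_1": "GAANNN", "O1_1": "GATNNN"})
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert count_fixed_nonsynonymous(aln, groups, "DC_vs_O") == 1


class TestRankTopFraction:
    def test_exactly_25_of_1000_distinct(self):
        values = np.arange(1000, dtype=float)
        mask = rank_top_fraction(values, 0.025)
        assert mask.sum() == 25
        assert mask[-25:].all()

    def test_cutoff_ties_all_included(self):
        values = np.array([0.0] * 96 + [5.0] * 4)
        mask = rank_top_fraction(values, 0.025)
        assert mask.sum() == 4  # all four tied at the cutoff value

    def test_degenerate_all_equal(self):
        mask = rank_top_fraction(np.ones(50), 0.025)
        assert mask.all()


class TestAssignOrigin:
    def test_d_identical_to_c(self):
        aln = _aln(
            {
                "C1_1": "ATGATGATGATG",
                "C2_1": "ATGATGATGATG",
                "D1_1": "ATGATGATGATG",
                "D2_1": "ATGATGATGATG",
                "O1_1": "CCCTTTGGGAAA",
                "O2_1": "CCCTTTGGGAAA",
            }
        )
        groups = GroupMap({"C1": "C", "C2": "C", "D1": "D", "D2": "D", "O1": "O", "O2": "O"})
        assert assign_origin(aln, groups) == "parentC"

    def test_exactly_intermediate_is_ambiguous(self):
        aln = _aln(
            {
                "C1_1": "AAAAAACCCCCC",
                "D1_1": "AAAAAAGGGGGG",  # equidistant from C and O
                "O1_1": "TTTTTTGGGGGG",
            }
        )
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert assign_origin(aln, groups) == "ambiguous"

    def test_single_unique_haplotype_ambiguous(self):
        aln = _aln({n: "ATGATG" for n in ("C1_1", "D1_1", "O1_1")})
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert assign_origin(aln, groups) == "ambiguous"

    def test_origin_swaps_with_parent_labels(self):
        seqs = {
            "C1_1": "ATGATGATGATGATGATG",
            "C2_1": "ATGATGATGATGATGATC",
            "D1_1": "CCCTTTGGGAAACCCTTT",
            "D2_1": "CCCTTTGGGAAACCCTTA",
            "O1_1": "CCCTTTGGGAAACCCTTT",
            "O2_1": "CCCTTTGGGAAACCCTGT",
        }
        aln = _aln(seqs)
        groups = GroupMap({"C1": "C", "C2": "C", "D1": "D", "D2": "D", "O1": "O", "O2": "O"})
        assert assign_origin(aln, groups) == "parentO"
        swapped = GroupMap(
            {"C1": "O", "C2": "O", "D1": "D", "D2": "D", "O1": "C", "O2": "C"}
        )
        assert assign_origin(aln, swapped) == "parentC"


class TestAlternatingFixedAa:
    def test_planted_two_one(self):
        # col1: C=AAA(K) O=GAA(E) D=AAA -> from C
        # col2: C=CGT(R) O=CAT(H) D=CGT -> from C
        # col3: C=GAA(E) O=GAT(D) D=GAT -> from O
        mk = lambda c1, c2, c3: c1 + c2 + c3
        aln = _aln(
            {
                "C1_1": mk("AAA", "CGT", "GAA"),
                "C2_1": mk("AAA", "CGT", "GAA"),
                "D1_1": mk("AAA", "CGT", "GAT"),
                "D2_1": mk("AAA", "CGT", "GAT"),
                "O1_1": mk("GAA", "CAT", "GAT"),
                "O2_1": mk("GAA", "CAT", "GAT"),
            }
        )
        groups = GroupMap({"C1": "C", "C2": "C", "D1": "D", "D2": "D", "O1": "O", "O2": "O"})
        assert alternating_fixed_aa(aln, groups) == (2, 1)

    def test_no_fixed_differences(self):
        aln = _aln({n: "GAAGAT" for n in ("C1_1", "D1_1", "O1_1")})
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        assert alternating_fixed_aa(aln, groups) == (0, 0)

    def test_random_fixture_matches_positionwise_scan(self, rng):
        """Fifty random codon columns checked against a brute-force scan."""
        from Bio.Seq import Seq

        bases = np.array(list("ACGT"))
        cols_c = ["".join(rng.choice(bases, 3)) for _ in range(50)]
        cols_o = ["".join(rng.choice(bases, 3)) for _ in range(50)]
        pick_c = rng.random(50) < 0.5
        cols_d = [c if p else o for c, o, p in zip(cols_c, cols_o, pick_c)]
        aln = _aln(
            {
                "C1_1": "".join(cols_c),
                "D1_1": "".join(cols_d),
                "O1_1": "".join(cols_o),
            }
        )
        groups = GroupMap({"C1": "C", "D1": "D", "O1": "O"})
        exp_c = exp_o = 0
        for cc, cd, co in zip(cols_c, cols_d, cols_o):
            aas = [str(Seq(x).translate()) for x in (cc, cd, co)]
            if "*" in aas:
                continue
            if aas[0] != aas[2]:
                exp_c += aas[1] == aas[0]
                exp_o += aas[1] == aas[2]
        assert alternating_fixed_aa(aln, groups) == (exp_c, exp_o)


class TestCalls:
    def _toy_scan(self):
        """Three genes: one selected-from-C, one recombinant, one neutral."""
        neutral = {
            "C1_1": "AAAGAACGT" * 10,
            "C2_1": "AAGGAACGT" * 10,  # within-pair polymorphism (synonymous)
            "D1_1": "AAAGAACGT" * 10,
            "D2_1": "AAAGAGCGT" * 10,
            "O1_1": "AAAGAACGA" * 10,  # one synonymous fixed difference per repeat
            "O2_1": "AAAGAACGA" * 10,
        }
        selected = {
            "C1_1": "GAAGAAGAA" * 10,
            "C2_1": "GAAGAAGAA" * 10,
            "D1_1": "GAAGAAGAA" * 10,
            "D2_1": "GAAGAAGAA" * 10,
            "O1_1": "GATGATGAT" * 10,  # every codon a replacement
            "O2_1": "GATGATGAT" * 10,
        }
        return neutral, selected

    def test_hybrid_signal_requires_both_groupings(self):
        neutral, selected = self._toy_scan()
        alns = [
            _aln(selected, "sel"),
            _aln(neutral, "neu1"),
            _aln(neutral, "neu2"),
        ]
        stats = gene_stats(alns, GROUPS_2EACH)
        # 'sel' passes both criteria only under DC_vs_O -> no hybrid signal
        assert call_hybrid_signal(stats) == []
        sub = stats[(stats.gene == "sel") & (stats.grouping == "DC_vs_O")].iloc[0]
        assert sub.N_fix == 30
        assert sub.hka_p < 0.01

    def test_threshold_excludes_p_above_alpha(self):
        neutral, selected = self._toy_scan()
        alns = [_aln(selected, "sel"), _aln(neutral, "neu")]
        stats, calls = scan_genes(alns, GROUPS_2EACH, hka_alpha=1e-300)
        assert calls.psg_from_c == [] and calls.psg_from_o == []

    def test_selected_gene_called_from_c(self):
        neutral, selected = self._toy_scan()
        alns = [_aln(selected, "sel")] + [
            _aln(neutral, f"neu{i}") for i in range(9)
        ]
        stats, calls = scan_genes(alns, GROUPS_2EACH)
        assert calls.psg_from_c == ["sel"]
        assert calls.psg_from_o == []
        assert calls.origin["sel"] == "parentC"
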