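"""Accessibility metrics against independent brute-force oracles.

The oracles below are deliberately written with plain loops over explicit
codon strings, independent of the vectorized implementation they check.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from evocode.codes import CODONS, GeneticCode, standard_code
from evocode.datagen import synthetic_substitutions
from evocode.metrics import (
    UndefinedRatioError,
    access_distribution,
    combined_fitness,
    edge_census,
    edge_list,
    evolvability,
    f_chem,
    f_ratio,
    f_unique,
    min_replacements,
    penalized_fitness,
    snr_neighbors,
    substitution_analysis,
    unique_access,
)

BASES = "TCAG"


def oracle_neighbors(codon):
    return {
        codon[:i] + b + codon[i + 1:]
        for i in range(3)
        for b in BASES
        if b != codon[i]
    }


def oracle_unique_access(code, codon):
    return len({code[n] for n in oracle_neighbors(codon)} - {code[codon]})


def oracle_incoming(code):
    counts = {}
    for c in CODONS:
        for n in oracle_neighbors(c):
            a, b = code[c], code[n]
            if a != b and a != "*" and b != "*":
                counts[b] = counts.get(b, 0) + 1
    return counts


@pytest.fixture(scope="module")
def constant_code():
    """All 64 codons -> alanine (plus one forced stop-free flag)."""
    return GeneticCode("A" * 64, stopless=True, require_all_residues=False)


class TestNeighborhood:
    def test_aaa_neighbors(self):
        assert snr_neighbors("AAA") == {
            "CAA", "GAA", "TAA", "ACA", "AGA", "ATA", "AAC", "AAG", "AAT"
        }

    @pytest.mark.parametrize("codon", ["TTT", "TGG", "GCA", "ATG"])
    def test_nine_neighbors_excluding_self(self, codon):
        nbrs = snr_neighbors(codon)
        assert len(nbrs) == 9
        assert codon not in nbrs
        assert nbrs == oracle_neighbors(codon)

    def test_tgg_reaches_two_stops(self):
        assert {"TGA", "TAG"} <= snr_neighbors("TGG")


class TestUniqueAccess:
    @pytest.mark.parametrize("codon,expected", [("GCT", 6), ("TGG", 6)])
    def test_standard_examples(self, std, codon, expected):
        assert unique_access(std, codon) == expected
        assert oracle_unique_access(std, codon) == expected

    def test_matches_oracle_on_random_codes(self, random_codes):
        for code in random_codes[:10]:
            for codon in CODONS[::7]:
                assert unique_access(code, codon) == oracle_unique_access(code, codon)

    def test_constant_code_zero(self, constant_code):
        assert unique_access(constant_code, "AAA") == 0


class TestAccessDistribution:
    def test_standard_statistics(self, std):
        mean, sd, lo, hi = access_distribution(std)
        assert round(mean, 1) == 6.1
        assert round(sd, 2) == 0.69
        assert (lo, hi) == (5, 7)
        assert mean == f_unique(std)

    def test_constant_code(self, constant_code):
        assert access_distribution(constant_code) == (0.0, 0.0, 0, 0)

    def test_bounds_on_random_codes(self, random_codes):
        for code in random_codes:
            assert 0.0 <= f_unique(code) <= 9.0


class TestFRatio:
    def test_standard_matches_exhaustive_enumeration(self, std):
        counts = oracle_incoming(std)
        expected = min(counts.values()) / max(counts.values())
        assert f_ratio(std) == pytest.approx(expected)

    def test_random_codes_match_oracle(self, random_codes):
        for code in random_codes[:10]:
            counts = oracle_incoming(code)
            expected = min(
                counts.get(aa, 0) for aa in set(code.translation) - {"*"}
            ) / max(counts.values())
            assert f_ratio(code) == pytest.approx(expected)

    def test_constant_code_undefined(self, constant_code):
        with pytest.raises(UndefinedRatioError):
            f_ratio(constant_code)


class TestFChem:
    def test_standard_calibration(self, std, classes):
        assert round(f_chem(std, classes), 2) == 5.53

    def test_constant_code_zero(self, constant_code, classes):
        assert f_chem(constant_code, classes) == 0.0

    def test_bounded_by_nine(self, random_codes, classes):
        for code in random_codes[:10]:
            assert 0.0 <= f_chem(code, classes) <= 9.0
            distinct = f_chem(code, classes, distinct=True)
            assert distinct <= min(9, classes.class_count + 1)


class TestCombinedAndPenalized:
    def test_standard_composition(self, std, classes):
        rep = combined_fitness(std, classes, std)
        assert rep.f_combined == pytest.approx(
            (rep.f_unique / 9) * rep.f_ratio * (rep.f_chem / 9)
        )
        assert rep.f_combined <= 1.0
        assert rep.reassignments == 0

    def test_penalty_arithmetic(self, std, classes):
        two = std.with_assignment("TAG", "N").with_assignment("TGA", "N")
        base = combined_fitness(two, classes, std).f_combined
        lin = penalized_fitness(two, std, classes, alpha=0.9, exponent=1)
        sq = penalized_fitness(two, std, classes, alpha=0.9, exponent=2)
        assert lin.penalized_f == pytest.approx(base * 0.9**2)
        assert sq.penalized_f == pytest.approx(base * 0.9**4)
        none = penalized_fitness(std, std, classes, alpha=0.9)
        assert none.penalized_f == pytest.approx(none.f_combined)

    def test_alpha_validation(self, std, classes):
        with pytest.raises(ValueError):
            penalized_fitness(std, std, classes, alpha=1.5)


class TestEdgeCensus:
    def test_standard_counts(self, std, classes):
        census = edge_census(std, classes)
        assert census.synonymous == 67
        assert census.stop_involving == 25
        assert census.within_class == 42
        assert census.red_edges == 109
        assert census.total == 288

    def test_partition_invariant_on_random_codes(self, classes):
        from evocode.datagen import random_code

        for seed in range(1000):
            census = edge_census(random_code(seed), classes)
            assert census.total == 288

    def test_constant_code_all_synonymous(self, constant_code, classes):
        census = edge_census(constant_code, classes)
        assert census.synonymous == 288
        assert census.within_class == census.between_class == census.stop_involving == 0

    def test_edge_list_agrees_with_census(self, std, classes):
        table = edge_list(std, classes)
        counts = table["category"].value_counts()
        census = edge_census(std, classes)
        assert counts["synonymous"] == census.synonymous
        assert counts["within_class"] == census.within_class
        assert len(table) == 288


class TestMinReplacements:
    def test_standard_examples(self, std):
        mat = min_replacements(std)
        assert mat.loc["L", "L"] == 0
        assert mat.loc["M", "W"] == 2
        assert mat.loc["F", "K"] == 3

    def test_symmetry_diagonal_and_oracle(self, std, random_codes):
        for code in random_codes[:50]:
            mat = min_replacements(code)
            assert (mat.values.T == mat.values).all()
            assert (np.diag(mat.values) == 0).all()
        # brute-force oracle spot check on a handful of codes
        for code in random_codes[:5]:
            mat = min_replacements(code)
            for a, b in [("A", "W"), ("C", "K"), ("M", "P")]:
                expected = min(
                    sum(x != y for x, y in zip(ca, cb))
                    for ca in code.codons_for(a)
                    for cb in code.codons_for(b)
                )
                assert mat.loc[a, b] == expected


class TestSubstitutionAnalysis:
    def test_mass_on_snr_pairs_gives_negative_rho(self, std):
        mat = min_replacements(std)
        rows = [
            {"wt": a, "mut": b, "count": 100 if mat.loc[a, b] == 1 else 0}
            for a, b in itertools.permutations("ACDEFGHIKLMNPQRSTVWY", 2)
        ]
        _, rho, _ = substitution_analysis(pd.DataFrame(rows), std)
        assert rho < 0

    def test_synthetic_bias_recovered(self, std):
        table = synthetic_substitutions(std, snr_bias=20, n=10_000, seed=1)
        _, rho, p = substitution_analysis(table, std)
        assert rho < -0.5
        assert p < 1e-6

    def test_unbiased_counts_give_weak_association(self, std):
        table = synthetic_substitutions(std, snr_bias=1.0, n=100_000, seed=1)
        _, rho, _ = substitution_analysis(table, std)
        assert abs(rho) < 0.2

    def test_empty_table_rejected(self, std):
        with pytest.raises(ValueError):
            substitution_analysis(pd.DataFrame(columns=["wt", "mut", "count"]), std)


class TestEvolvability:
    def test_triplet_of_alanines(self, std):
        assert evolvability("GCTGCTGCT", std) == 6.0

    def test_single_codon_equals_unique_access(self, std):
        for codon in ["ATG", "TGG", "AAA"]:
            assert evolvability(codon, std) == unique_access(std, codon)

    def test_linearity_as_mean_of_codons(self, std):
        gene = "ATGGCTTGGAAA"
        per_codon = [
            unique_access(std, gene[i : i + 3]) for i in range(0, len(gene), 3)
        ]
        assert evolvability(gene, std) == pytest.approx(np.mean(per_codon))

    def test_constant_code_zero(self, constant_code):
        assert evolvability("AAAGGG", constant_code) == 0.0

    @pytest.mark.parametrize("bad", ["", "AT", "ATGG"])
    def test_bad_input_rejected(self, std, bad):
        with pytest.raises(ValueError):
            evolvability(bad, std)
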