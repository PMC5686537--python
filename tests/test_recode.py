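"""Folding backends and structure-preserving recoding."""

import itertools

import numpy as np
import pytest

from evocode.codes import GeneticCode, standard_code
from evocode.datagen import GeneSpec, random_code, random_gene
from evocode.recode import (
    FoldResult,
    RecodingConfig,
    UnencodableError,
    fold,
    recode_gene,
    recode_leader,
    structure_distance,
)


class TestFold:
    def test_hairpin_oracle(self):
        r = fold("GGGAAACCC")
        assert r.structure == "(((...)))"
        assert r.energy == -3.0

    def test_unpairable_sequence(self):
        r = fold("AAAAAAAAA")
        assert r.structure == "." * 9
        assert r.energy == 0.0

    def test_structure_balanced_and_same_length(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
            r = fold(seq)
            assert len(r.structure) == len(seq)
            assert r.structure.count("(") == r.structure.count(")")
            r.pairs()  # raises if unbalanced

    def test_min_hairpin_loop_respected(self):
        # GC pair would need a 2-base loop; forbidden
        assert fold("GAAC").structure == "...."

    def test_pair_count_never_negative(self):
        assert fold("ACGTACGTACGT").energy <= 0

    def test_rna_input_accepted(self):
        assert fold("GGGAAACCC") == fold("GGGAAACCC".replace("T", "U"))

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold("GGXAAACCC")


class TestStructureDistance:
    def test_identity_zero(self):
        r = fold("GGGAAACCC")
        assert structure_distance(r, r) == 0

    def test_pairset_difference(self):
        a = FoldResult("(((...)))", -3.0)
        b = FoldResult(".........", 0.0)
        assert structure_distance(a, b) == 3
        assert structure_distance(b, a) == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structure_distance(FoldResult("...", 0.0), FoldResult("....", 0.0))


@pytest.fixture(scope="module")
def small_config():
    return RecodingConfig(candidate_cap=200, seed=0)


GENE60 = "ATGGCTAAACGTGAAGATCTGTTCGGTAGCACCATTGTTAACCAGTGGCTGCGTTCTTAA"


class TestRecodeLeader:
    def test_identity_when_source_equals_target(self, std, small_config):
        leader, diag = recode_leader("AGGA", GENE60, std, std, small_config)
        assert leader == GENE60[:39]
        assert diag.bp_distance == 0
        assert diag.recoded_energy == diag.wt_energy

    def test_unencodable_residue_reported(self, std, small_config):
        # target with no tryptophan codon at all
        translation = std.translation.replace("W", "C")
        target = GeneticCode(translation, require_all_residues=False)
        gene = "ATG" + "TGG" * 13 + "TAA"
        with pytest.raises(UnencodableError) as err:
            recode_leader("AGGA", gene, std, target, small_config)
        assert "W" in str(err.value)

    def test_exhaustive_scan_returns_optimum(self, std):
        """With scan fraction 1.0 the chosen leader is the true optimum."""
        cfg = RecodingConfig(
            leader_cds_length=9, leader_scan_fraction=1.0, candidate_cap=10**6,
            seed=0,
        )
        gene = "ATGGCTCGTTAA"
        leader, diag = recode_leader("AGGA", gene, std, std, cfg)
        protein = std.translate(gene[:9])
        wt = fold("AGGA" + gene[:9])
        best = min(
            (
                abs(fold("AGGA" + "".join(combo)).energy - wt.energy)
                + structure_distance(fold("AGGA" + "".join(combo)), wt)
                for combo in itertools.product(
                    *(std.codons_for(aa) for aa in protein)
                )
            )
        )
        score = abs(diag.recoded_energy - diag.wt_energy) + diag.bp_distance
        assert score == pytest.approx(best)


class TestRecodeGene:
    def test_identity_recode(self, std, small_config):
        result = recode_gene("AGGA", GENE60, std, std, small_config)
        assert result.recoded == GENE60
        assert result.translation_preserved

    def test_translation_preserved_on_random_pairs(self, std):
        cfg = RecodingConfig(candidate_cap=30, seed=0)
        for seed in range(100):
            code = random_code(seed, n_stops=3)
            gene = random_gene(GeneSpec(length=15, seed=seed), std)
            result = recode_gene("AGGA", gene, std, code, cfg)
            assert code.translate(result.recoded) == std.translate(gene)

    def test_deterministic_under_seed(self, std):
        cfg = RecodingConfig(candidate_cap=50, seed=42)
        code = random_code(3, n_stops=3)
        gene = random_gene(GeneSpec(length=25, seed=9), std)
        a = recode_gene("AGGA", gene, std, code, cfg)
        b = recode_gene("AGGA", gene, std, code, cfg)
        assert a.recoded == b.recoded

    def test_region_tiling_covers_gene(self, std, small_config):
        gene = random_gene(GeneSpec(length=40, seed=1), std)
        result = recode_gene("AGGA", gene, std, std, small_config)
        covered = sum(r.length for r in result.regions)
        assert covered == len(gene)
        assert result.regions[0].region == "leader"

    def test_leader_tracks_wildtype_better_than_random_recoding(self, std):
        """Paired comparison: the scanning recoder's leader matches the
        wild-type fold (energy + structure score) better on average than a
        random synonymous recoding of the same genes."""
        from evocode.recode import structure_distance

        cfg = RecodingConfig(candidate_cap=60, seed=0)
        code = random_code(11, n_stops=3)
        scores_opt, scores_rand = [], []
        for seed in range(20):
            gene = random_gene(GeneSpec(length=17, seed=100 + seed), std)
            result = recode_gene("AGGA", gene, std, code, cfg)
            leader_diag = result.regions[0]
            scores_opt.append(
                abs(leader_diag.recoded_energy - leader_diag.wt_energy)
                + leader_diag.bp_distance
            )
            rng = np.random.default_rng(seed)
            protein = std.translate(gene[: leader_diag.length])
            rand = "".join(
                code.codons_for(aa)[rng.integers(len(code.codons_for(aa)))]
                for aa in protein
            )
            wt = fold("AGGA" + gene[: leader_diag.length])
            rf = fold("AGGA" + rand)
            scores_rand.append(
                abs(rf.energy - wt.energy) + structure_distance(rf, wt)
            )
        assert np.mean(scores_opt) < np.mean(scores_rand)
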