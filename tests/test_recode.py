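"""Harmonization, the most-frequent baseline, and motif avoidance."""

import numpy as np
import pytest

from codonharmony import (
    CodingSequence,
    MotifConstraint,
    MotifUnavoidableError,
    STANDARD_CODE,
    avoid_motifs,
    chi,
    harmonize,
    profile,
    recode_most_frequent,
)
from codonharmony.recode import find_motif_occurrences, reverse_complement

from conftest import enumerate_synonymous_variants, random_cds


@pytest.fixture
def gly_tables(make_table):
    # native Gly RCA {GGT:1.0, GGC:0.4, GGA:0.2, GGG:0.1}
    native = make_table({"GGT": 10, "GGC": 4, "GGA": 2, "GGG": 1})
    # expression Gly RCA {GGT:0.3, GGC:1.0, GGA:0.6, GGG:0.05}
    expr = make_table({"GGT": 6, "GGC": 20, "GGA": 12, "GGG": 1})
    return native, expr


class TestHarmonize:
    def test_closest_rca_pick_in_gly_family(self, gly_tables):
        """GGC (native RCA 0.4) maps to GGT (expr RCA 0.3, |delta| 0.1),
        the closest of the four candidates (0.1 < 0.2, 0.35, 0.6)."""
        native, expr = gly_tables
        result = harmonize(CodingSequence("g", "GGC"), native, expr)
        assert result.output_seq.dna == "GGT"
        rec = result.per_position[0]
        assert (rec.rca_native, rec.rca_expr_chosen) == (0.4, 0.3)
        assert rec.abs_delta == pytest.approx(0.1)

    def test_self_harmonization_is_identity(self, host_pair):
        (table, cds), _ = host_pair
        for seq in cds[:3]:
            result = harmonize(seq, table, table)
            assert result.output_seq.dna == seq.dna
            assert result.chi_after == 0.0

    def test_translation_preserved(self, host_pair):
        (table_a, cds), (table_b, _) = host_pair
        for seq in cds[:5]:
            result = harmonize(seq, table_a, table_b)
            assert result.output_seq.translate() == seq.translate()

    def test_chi_never_increases(self, host_pair):
        (table_a, cds), (table_b, _) = host_pair
        for seq in cds[:10]:
            result = harmonize(seq, table_a, table_b)
            assert result.chi_after <= result.chi_before + 1e-12

    def test_brute_force_chi_minimality_small_genes(self, host_pair):
        """Greedy per-position choice attains the exact CHI minimum over
        ALL synonymous variants (CHI is a sum of independent terms)."""
        (table_a, _), (table_b, _) = host_pair
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 40:
            seq = random_cds(rng, rng.integers(3, 9))
            n_variants = int(
                np.prod([len(STANDARD_CODE.synonymous_codons(c)) for c in seq.codons])
            )
            if n_variants > 5000:
                continue
            p_native = profile(seq, table_a)
            best = min(
                chi(profile(CodingSequence("v", "".join(v)), table_b), p_native)
                for v in enumerate_synonymous_variants(seq)
            )
            result = harmonize(seq, table_a, table_b)
            assert result.chi_after == pytest.approx(best, abs=1e-12)
            checked += 1

    def test_idempotence_against_native_wild_type_profile(self, host_pair):
        """Re-applying the per-position rule to a harmonized gene, with
        the targets still taken from the wild-type's native profile, is
        a fixed point."""
        from codonharmony.recode import _ranked_candidates

        (table_a, cds), (table_b, _) = host_pair
        seq = cds[0]
        once = harmonize(seq, table_a, table_b)
        for cin, cout in zip(seq.codons, once.output_seq.codons):
            again = _ranked_candidates(cout, table_b, table_a.rca[cin])[0]
            assert again == cout
        # plain determinism: the same call gives the same output
        assert harmonize(seq, table_a, table_b).output_seq.dna == once.output_seq.dna

    def test_tie_breaks_toward_higher_expr_rca_then_alphabetical(self, make_table):
        # native GGA RCA 0.5; expr GGT and GGC both RCA 0.5 -> equally close,
        # both ties on RCA too -> alphabetical GGC wins
        native = make_table({"GGT": 10, "GGC": 1, "GGA": 5, "GGG": 1})
        expr = make_table({"GGT": 5, "GGC": 5, "GGA": 10, "GGG": 1})
        result = harmonize(CodingSequence("g", "GGA"), native, expr)
        assert result.output_seq.dna == "GGC"
        # higher-RCA preference: native GGG RCA 0.1; expr candidates GGT 0.5,
        # GGC 0.5, GGG 0.1 -> exact match GGG wins outright
        result2 = harmonize(CodingSequence("g", "GGG"), native, expr)
        assert result2.output_seq.dna == "GGG"

    def test_mismatched_codes_rejected(self, make_table):
        from dataclasses import replace
        from codonharmony.genetic_code import GeneticCode

        t1 = make_table({})
        t2 = replace(t1, code=GeneticCode.from_table_id(11))
        from codonharmony.usage_tables import counts_to_rca

        t2 = counts_to_rca(t2)
        with pytest.raises(ValueError, match="genetic codes"):
            harmonize(CodingSequence("g", "ATGTAA"), t1, t2)


class TestMostFrequentBaseline:
    def test_cai_is_exactly_one(self, host_pair):
        (_, cds), (table_b, _) = host_pair
        for seq in cds[:5]:
            result = recode_most_frequent(seq, table_b)
            assert result.cai_after == 1.0
            assert result.output_seq.translate() == seq.translate()

    def test_family_maximum_chosen(self, gly_tables):
        _, expr = gly_tables  # expr Gly max is GGC
        assert recode_most_frequent(CodingSequence("g", "GGT"), expr).output_seq.dna == "GGC"

    def test_harmonized_chi_not_above_most_frequent_chi(self, host_pair):
        (table_a, cds), (table_b, _) = host_pair
        for seq in cds[:5]:
            p_native = profile(seq, table_a)
            chi_h = harmonize(seq, table_a, table_b).chi_after
            chi_f = chi(
                profile(recode_most_frequent(seq, table_b).output_seq, table_b),
                p_native,
            )
            assert chi_h <= chi_f + 1e-12


class TestMotifAvoidance:
    def test_ecori_site_removed_protein_preserved(self, make_table):
        table = make_table({})
        seq = CodingSequence("g", "ATGGAATTCTAA")  # Glu-Phe spells GAATTC
        constraint = MotifConstraint(["GAATTC"])
        result = harmonize(seq, table, table, constraints=constraint)
        assert "GAATTC" not in result.output_seq.dna
        assert reverse_complement("GAATTC") not in result.output_seq.dna
        assert result.output_seq.translate() == "MEF*"
        assert result.substitutions_for_motifs  # logged positions

    def test_no_motif_leaves_result_unchanged(self, host_pair):
        (table_a, cds), (table_b, _) = host_pair
        seq = cds[1]
        plain = harmonize(seq, table_a, table_b)
        constrained = harmonize(
            seq, table_a, table_b, constraints=MotifConstraint(["A" * 30])
        )
        assert constrained.output_seq.dna == plain.output_seq.dna
        assert constrained.substitutions_for_motifs == []

    def test_motif_through_single_codon_families_is_unavoidable(self, make_table):
        table = make_table({})
        seq = CodingSequence("g", "ATGTGGTAA")  # Met-Trp: no alternatives
        with pytest.raises(MotifUnavoidableError, match="ATGTGG"):
            harmonize(seq, table, table, constraints=MotifConstraint(["ATGTGG"]))

    def test_reverse_strand_sites_found_and_removed(self, make_table):
        table = make_table({})
        # BsaI site GGTCTC; plant its reverse complement GAGACC in frame
        seq = CodingSequence("g", "ATGGAGACCTAA")
        constraint = MotifConstraint(["GGTCTC"], scan_both_strands=True)
        result = harmonize(seq, table, table, constraints=constraint)
        out = result.output_seq.dna
        assert "GGTCTC" not in out and "GAGACC" not in out
        assert result.output_seq.translate() == seq.translate()
        # with scanning disabled the given strand is already clean
        untouched = harmonize(
            seq, table, table,
            constraints=MotifConstraint(["GGTCTC"], scan_both_strands=False),
        )
        assert untouched.output_seq.dna == seq.dna

    def test_each_substitution_reduces_occurrences(self, host_pair):
        (table_a, cds), (table_b, _) = host_pair
        constraint = MotifConstraint(["GAATTC", "GGATCC", "CTGCAG"])
        for seq in cds[:8]:
            result = harmonize(seq, table_a, table_b, constraints=constraint)
            assert find_motif_occurrences(result.output_seq.dna, constraint.search_set) == []
            assert result.output_seq.translate() == seq.translate()
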