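"""NG86 dN/dS counting, comparison-set selection, and the divergence index."""

from __future__ import annotations

import numpy as np
import pytest

from genestrata.divergence import (
    STOP_CODONS,
    CodonSequence,
    ComparisonSpec,
    divergence_index,
    ng86_pair,
    select_comparison_species,
)
from genestrata.fixtures import gen_codon_pair

from .oracles import ng86_diff_oracle, ng86_site_oracle


def _seq(nt, gene="g", species="sp"):
    return CodonSequence(gene, species, nt)


def _random_pair(rng, n_codons):
    """Two random stop-free codon sequences of equal length."""

    def draw():
        out = []
        while len(out) < n_codons:
            codon = "".join(rng.choice(list("ACGT"), size=3))
            if codon not in STOP_CODONS:
                out.append(codon)
        return "".join(out)

    return _seq(draw(), species="a"), _seq(draw(), species="b")


class TestCodonSequenceValidation:
    def test_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            _seq("ACGTA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            _seq("ATGTAAAAA")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            _seq("ATGNNN")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _seq("")


class TestNg86Pair:
    def test_identical_sequences_flagged_ds_zero(self):
        a = _seq("ATGGCTAAA")
        result = ng86_pair(a, _seq("ATGGCTAAA", species="b"))
        assert result.syn_diffs == result.nonsyn_diffs == 0
        assert result.dN == 0 and result.dS == 0
        assert result.ratio is None and result.excluded == "dS_zero"

    def test_single_synonymous_change_counts(self):
        # Lys AAA -> AAG is synonymous; the 2-codon pair has so few
        # synonymous sites (S = 1/3) that pS saturates the correction.
        result = ng86_pair(_seq("ATGAAA"), _seq("ATGAAG", species="b"))
        assert result.syn_diffs == 1 and result.nonsyn_diffs == 0
        assert result.excluded == "correction_out_of_range"

    def test_synonymous_change_in_context_gives_zero_ratio(self):
        # Same Lys substitution padded with synonymous-site-rich codons:
        # dN = 0, dS > 0, ratio = 0.
        pad = "CTGGGACCGTCC"  # Leu/Gly/Pro/Ser, each with a 4-fold site
        result = ng86_pair(
            _seq("ATGAAA" + pad), _seq("ATGAAG" + pad, species="b")
        )
        assert result.nonsyn_diffs == 0 and result.syn_diffs == 1
        assert result.dN == 0 and result.dS > 0
        assert result.ratio == 0.0 and result.excluded is None

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ng86_pair(_seq("ATGAAA"), _seq("ATG", species="b"))

    def test_sites_sum_to_sequence_length(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            a, b = _random_pair(rng, int(rng.integers(1, 30)))
            result = ng86_pair(a, b)
            assert result.syn_sites + result.nonsyn_sites == pytest.approx(
                len(a.nt), abs=1e-9
            )

    def test_symmetry(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            a, b = _random_pair(rng, int(rng.integers(1, 10)))
            fwd, rev = ng86_pair(a, b), ng86_pair(b, a)
            assert fwd.syn_diffs == pytest.approx(rev.syn_diffs)
            assert fwd.nonsyn_diffs == pytest.approx(rev.nonsyn_diffs)
            assert fwd.syn_sites == pytest.approx(rev.syn_sites)

    def test_difference_counts_match_pathway_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a, b = _random_pair(rng, int(rng.integers(1, 6)))
            result = ng86_pair(a, b)
            sd, nd = ng86_diff_oracle(a.nt, b.nt)
            assert result.syn_diffs == pytest.approx(sd, abs=1e-12)
            assert result.nonsyn_diffs == pytest.approx(nd, abs=1e-12)

    def test_site_counts_match_translation_oracle(self):
        rng = np.random.default_rng(24)
        for _ in range(50):
            a, b = _random_pair(rng, int(rng.integers(1, 8)))
            result = ng86_pair(a, b)
            sa, _ = ng86_site_oracle(a.nt)
            sb, _ = ng86_site_oracle(b.nt)
            assert result.syn_sites == pytest.approx((sa + sb) / 2, abs=1e-12)

    def test_selection_regime_direction(self):
        """Planted synonymous-only pairs give dN = 0; nonsynonymous-only
        pairs give dS = 0 (flagged); mixed with more synonymous pressure
        keeps the ratio below 1."""
        a, b, _ = gen_codon_pair(1, 200, syn_subs=8, nonsyn_subs=0)
        result = ng86_pair(a, b)
        assert result.dN == 0 and result.dS > 0 and result.ratio == 0
        a, b, _ = gen_codon_pair(2, 200, syn_subs=0, nonsyn_subs=8)
        result = ng86_pair(a, b)
        assert result.excluded == "dS_zero" and result.dN > 0
        a, b, _ = gen_codon_pair(3, 2000, syn_subs=60, nonsyn_subs=20)
        result = ng86_pair(a, b)
        assert result.ratio is not None and result.ratio < 1

    def test_estimator_is_recorded(self):
        result = ng86_pair(_seq("ATGAAA"), _seq("ATGAAA", species="b"))
        assert result.estimator == "NG86-JC"


class TestSelectComparisonSpecies:
    def test_level_one_within_genus_is_empty_here(self, toy_primates):
        assert (
            select_comparison_species("hsa", toy_primates, ComparisonSpec(level=1))
            == set()
        )

    def test_level_two_reaches_the_family(self, toy_primates):
        assert select_comparison_species(
            "hsa", toy_primates, ComparisonSpec(level=2)
        ) == {"ptr", "ggo"}

    def test_level_three_reaches_everything(self, toy_primates):
        assert select_comparison_species(
            "hsa", toy_primates, ComparisonSpec(level=3)
        ) == {"ptr", "ggo", "mmu"}

    def test_explicit_organisms(self, toy_primates):
        assert select_comparison_species(
            "hsa", toy_primates, ComparisonSpec(organisms=("ggo",))
        ) == {"ggo"}

    def test_unknown_organism_code_errors(self, toy_primates):
        with pytest.raises(KeyError, match="xyz"):
            select_comparison_species(
                "hsa", toy_primates, ComparisonSpec(organisms=("xyz",))
            )

    def test_level_at_lineage_length_errors(self, toy_primates):
        with pytest.raises(ValueError, match="level"):
            select_comparison_species(
                "hsa", toy_primates, ComparisonSpec(level=4)
            )

    def test_spec_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            ComparisonSpec()
        with pytest.raises(ValueError):
            ComparisonSpec(level=1, organisms=("ggo",))


class TestDivergenceIndex:
    def test_single_homolog_equals_pair_ratio(self):
        a, b, _ = gen_codon_pair(5, 150, syn_subs=4, nonsyn_subs=3)
        pair = ng86_pair(a, b)
        result = divergence_index(a, [b])
        assert result.di == pytest.approx(pair.ratio)
        assert result.n_pairs_used == 1

    def test_mean_over_homologs(self):
        target, b1, _ = gen_codon_pair(6, 150, syn_subs=5, nonsyn_subs=2)
        # same seed redraws the same ancestor; different substitution mix
        target2, b2, _ = gen_codon_pair(6, 150, syn_subs=3, nonsyn_subs=1)
        assert target2.nt == target.nt
        r1 = ng86_pair(target, b1).ratio
        r2 = ng86_pair(target, b2).ratio
        result = divergence_index(target, [b1, b2])
        assert result.di == pytest.approx((r1 + r2) / 2)

    def test_excluded_pairs_are_counted_not_averaged(self):
        target, good, _ = gen_codon_pair(7, 150, syn_subs=5, nonsyn_subs=2)
        identical = CodonSequence(target.gene_id, "twin", target.nt)
        good_ratio = ng86_pair(target, good).ratio
        result = divergence_index(target, [identical, good])
        assert result.di == pytest.approx(good_ratio)
        assert result.n_pairs_used == 1 and result.n_pairs_excluded == 1

    def test_no_homologs_is_undefined(self):
        target, _, _ = gen_codon_pair(8, 30, syn_subs=1, nonsyn_subs=0)
        result = divergence_index(target, [])
        assert result.di is None and result.n_pairs_used == 0

    def test_mean_of_identical_ratios_is_that_ratio(self):
        target, hom, _ = gen_codon_pair(9, 150, syn_subs=5, nonsyn_subs=2)
        ratio = ng86_pair(target, hom).ratio
        result = divergence_index(target, [hom, hom, hom])
        assert result.di == pytest.approx(ratio)
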