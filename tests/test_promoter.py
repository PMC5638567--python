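"""Promoter-allele alignment, variant calling and CpG-island prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taqase as tq
from taqase.promoter import VariantKind
from oracles import alignment_score_bruteforce, cpg_islands_bruteforce


def seq(s, sid="s"):
    return tq.PromoterSequence(id=sid, residues=s)


class TestAlignPair:
    @pytest.mark.parametrize("a,b,score", [
        ("ACGT", "ACGT", 4.0),      # identity
        ("ACGTA", "ACTA", 2.0),     # one deletion: 4 matches - gap 2
        ("ACGT", "ACTT", 2.0),      # one mismatch, no gaps
    ])
    def test_small_examples(self, a, b, score):
        aln = tq.align_pair(seq(a), seq(b))
        assert aln.score == score
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            tq.PromoterSequence(id="e", residues="")

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=6),
           st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_score_matches_exhaustive_enumeration(self, a, b):
        aln = tq.align_pair(seq(a), seq(b))
        assert aln.score == alignment_score_bruteforce(a, b)

    def test_score_matches_oracle_on_random_8mers(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            a = "".join(rng.choice(bases, rng.integers(1, 9)))
            b = "".join(rng.choice(bases, rng.integers(1, 9)))
            assert tq.align_pair(seq(a), seq(b)).score == alignment_score_bruteforce(a, b)


class TestFindVariants:
    def test_identical_sequences_no_variants(self):
        aln = tq.align_pair(seq("ACGTACGT"), seq("ACGTACGT"))
        assert tq.find_variants(aln) == []

    def test_single_snp(self):
        aln = tq.align_pair(seq("ACGT"), seq("ACTT"))
        (v,) = tq.find_variants(aln)
        assert (v.position, v.kind, v.allele_a, v.allele_b) == (3, VariantKind.SNP, "G", "T")

    def test_planted_snp_and_deletion_recovered(self):
        a, b = tq.simulate_promoter_pair(seed=7)
        variants = tq.find_variants(tq.align_pair(a, b))
        assert len(variants) == 2
        snp = next(v for v in variants if v.kind is VariantKind.SNP)
        indel = next(v for v in variants if v.kind is VariantKind.DELETION)
        assert snp.position == 77
        assert indel.position == 231
        assert len(indel.allele_a) == 1 and indel.allele_b == ""

    def test_event_counts_symmetric_under_swap(self):
        a, b = tq.simulate_promoter_pair(seed=11)
        fwd = tq.find_variants(tq.align_pair(a, b))
        rev = tq.find_variants(tq.align_pair(b, a))
        count = lambda vs, kinds: sum(v.kind in kinds for v in vs)
        assert count(fwd, {VariantKind.SNP}) == count(rev, {VariantKind.SNP})
        indel_kinds = {VariantKind.INSERTION, VariantKind.DELETION}
        assert count(fwd, indel_kinds) == count(rev, indel_kinds)

    def test_adjacent_gaps_merge_into_one_indel(self):
        aln = tq.align_pair(seq("AAATTTCCCGGG"), seq("AAACCCGGG"))
        variants = tq.find_variants(aln)
        indels = [v for v in variants if v.kind is VariantKind.DELETION]
        assert len(indels) == 1
        assert indels[0].allele_a == "TTT"


class TestCpGIslands:
    def test_cg_repeat_is_one_full_length_island(self):
        (island,) = tq.predict_cpg_islands(seq("CG" * 300))
        assert (island.start, island.end, island.length) == (1, 600, 600)
        assert island.gc_fraction == pytest.approx(1.0)
        assert island.obs_exp_cpg == pytest.approx(2.0)

    def test_poly_a_has_no_islands(self):
        assert tq.predict_cpg_islands(seq("A" * 600)) == []

    def test_planted_island_called_once_overlapping_block(self):
        a, _ = tq.simulate_promoter_pair(seed=7, island_span=(200, 520))
        islands = tq.predict_cpg_islands(a)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.start <= 520 and isl.end >= 200  # overlaps the planted block
        assert isl.length >= 200
        assert isl.gc_fraction > 0.5
        assert isl.obs_exp_cpg > 0.6

    @pytest.mark.parametrize("builder", [
        lambda: "CG" * 300,
        lambda: "A" * 600,
        lambda: tq.simulate_promoter_pair(seed=7)[0].residues,
        lambda: tq.simulate_promoter_pair(seed=19, length=1000,
                                          island_span=(400, 750))[0].residues,
        lambda: ("AT" * 150) + ("CG" * 150) + ("TA" * 150),
    ])
    def test_agrees_with_bruteforce_window_oracle(self, builder):
        s = builder()
        expected = cpg_islands_bruteforce(s)
        got = [(i.start, i.end) for i in tq.predict_cpg_islands(seq(s))]
        assert got == expected

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert tq.predict_cpg_islands(seq("ACGT" * 10)) == []

    def test_gc_fraction_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(2)
        s = "".join(rng.choice(list("ACGT"), 400))
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp[ch] for ch in reversed(s))
        gc = lambda x: (x.count("C") + x.count("G")) / len(x)
        for start in range(0, 200, 37):
            w = s[start:start + 200]
            w_rc = rc[len(s) - start - 200:len(s) - start]
            assert gc(w) == pytest.approx(gc(w_rc))

    def test_palindromic_cg_repeat_identical_on_both_strands(self):
        s = "CG" * 300
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp[ch] for ch in reversed(s))
        assert [(i.start, i.end) for i in tq.predict_cpg_islands(seq(s))] == \
               [(i.start, i.end) for i in tq.predict_cpg_islands(seq(rc))]

    def test_n_bases_excluded_from_counts(self):
        (island,) = tq.predict_cpg_islands(seq("CG" * 290 + "N" * 20))
        assert island.gc_fraction == pytest.approx(1.0)


def test_simulated_pair_without_features_is_identical():
    a, b = tq.simulate_promoter_pair(seed=3, snp_pos=None, indel_pos=None,
                                     island_span=None)
    assert a.residues == b.residues
    assert tq.find_variants(tq.align_pair(a, b)) == []
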