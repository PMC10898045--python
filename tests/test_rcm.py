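import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circlearn.rcm import (FlankPair, all_words, derive_flanks,
                           rcm_feature_names, rcm_feature_vector, rcm_score,
                           reverse_complement, sweep_kl)
from circlearn.seqio import SequenceRecord
from circlearn.synthetic import SyntheticConfig, generate

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


def naive_h(left: str, right: str, k: int):
    """Independent all-words recount of the reverse-complement match score."""

    def count(hay, needle):
        return sum(1 for i in range(len(hay) - len(needle) + 1)
                   if hay[i:i + len(needle)] == needle)

    total = 0
    per_word = []
    for w in all_words(k):
        hi = min(count(left, w), count(right, reverse_complement(w)))
        per_word.append(hi)
        total += hi
    return per_word, total


class TestReverseComplement:
    def test_worked_examples(self):
        assert reverse_complement("AATTCCGG") == "CCGGAATT"
        assert reverse_complement("ACCGU") == "ACGGU"
        assert reverse_complement("") == ""

    def test_alphabet_follows_input(self):
        assert reverse_complement("AAUU") == "AAUU"
        assert reverse_complement("AATT") == "AATT"
        assert reverse_complement("ANT") == "ANT"

    def test_invalid_character_position(self):
        with pytest.raises(ValueError, match="position 2"):
            reverse_complement("ACXGT")

    @settings(max_examples=50, derandomize=True)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestDeriveFlanks:
    def test_terminal_policy(self):
        rec = SequenceRecord("r", "A" * 250 + "C" * 500 + "G" * 250)
        fl = derive_flanks(rec, L=250)
        assert fl.left == "A" * 250 and fl.right == "G" * 250

    def test_midpoint_padding(self):
        rec = SequenceRecord("r", "A" * 150 + "G" * 150)
        fl = derive_flanks(rec, L=250)
        assert fl.left == "A" * 150 + "N" * 100
        assert fl.right == "G" * 150 + "N" * 100

    def test_external_policy(self):
        source = {"r": FlankPair("ACGT", "TTTT")}
        rec = SequenceRecord("r", "ACGTACGT")
        assert derive_flanks(rec, L=4, flank_source=source).left == "ACGT"
        with pytest.raises(KeyError):
            derive_flanks(SequenceRecord("q", "ACGT"), flank_source=source)

    def test_unequal_external_flanks_rejected(self):
        with pytest.raises(ValueError):
            FlankPair("ACGT", "ACG")


class TestRcmScore:
    @pytest.mark.parametrize("left,right,k,expected", [
        ("AAAA", "TTTT", 2, 3),   # word AA: min(3, 3)
        ("AAAA", "AAAA", 2, 0),   # no complements on the right
        ("ACG", "CGT", 2, 2),     # AC and CG each contribute 1
    ])
    def test_hand_examples(self, left, right, k, expected):
        assert rcm_score(FlankPair(left, right), k).h_total == expected

    def test_oracle_equivalence_100_random_pairs(self, rng):
        for _ in range(100):
            L = int(rng.integers(5, 51))
            k = int(rng.integers(1, 4))
            left = "".join(rng.choice(list("ACGT"), L))
            right = "".join(rng.choice(list("ACGT"), L))
            prof = rcm_score(FlankPair(left, right), k)
            per_word, total = naive_h(left, right, k)
            assert prof.h_total == total
            assert prof.hi.tolist() == per_word

    def test_profile_invariants(self, rng):
        left = "".join(rng.choice(list("ACGT"), 30))
        right = "".join(rng.choice(list("ACGT"), 30))
        prof = rcm_score(FlankPair(left, right), k=2)
        assert len(prof.hi) == prof.D == 16
        assert prof.h_total == prof.hi.sum()
        assert (prof.hi >= 0).all()
        assert prof.counts_left.sum() == prof.L1

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            rcm_score(FlankPair("ACG", "ACG"), k=4)
        with pytest.raises(ValueError):
            rcm_score(FlankPair("ACG", "ACG"), k=0)

    def test_n_windows_contribute_nothing(self):
        prof = rcm_score(FlankPair("ANA", "TNT"), k=2)
        assert prof.counts_left.sum() == 0 and prof.h_total == 0

    @settings(max_examples=40, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=30),
           st.text(alphabet="ACGT", min_size=4, max_size=30))
    def test_swap_revcomp_invariance(self, left, right):
        """H is unchanged by (left, right) -> (rc(right), rc(left))."""
        n = min(len(left), len(right))
        left, right = left[:n], right[:n]
        h1 = rcm_score(FlankPair(left, right), k=2).h_total
        h2 = rcm_score(FlankPair(reverse_complement(right),
                                 reverse_complement(left)), k=2).h_total
        assert h1 == h2

    def test_planted_pair_monotonicity(self, rng):
        for _ in range(20):
            left = "".join(rng.choice(list("ACGT"), 20))
            right = "".join(rng.choice(list("ACGT"), 20))
            h0 = rcm_score(FlankPair(left, right), k=3).h_total
            word = "".join(rng.choice(list("ACGT"), 3))
            h1 = rcm_score(FlankPair(left + word,
                                     right + reverse_complement(word)),
                           k=3).h_total
            assert h1 >= h0


class TestFeatureVector:
    def test_block_dimension_is_voc_plus_total(self):
        vec = rcm_feature_vector(FlankPair("ACGTACGT", "ACGTACGT"), k=3)
        assert len(vec) == 4 ** 3 + 1
        assert rcm_feature_names(3)[-1] == "rcm_total"
        assert vec["rcm_total"] == vec.drop("rcm_total").sum()

    def test_all_n_flanks_zero_block(self):
        vec = rcm_feature_vector(FlankPair("N" * 10, "N" * 10), k=2)
        assert (vec == 0).all()

    def test_palindromic_swap_same_total(self, rng):
        left = "".join(rng.choice(list("ACGT"), 15))
        right = "".join(rng.choice(list("ACGT"), 15))
        v1 = rcm_feature_vector(FlankPair(left, right), k=2)
        v2 = rcm_feature_vector(
            FlankPair(reverse_complement(right), reverse_complement(left)),
            k=2)
        assert v1["rcm_total"] == v2["rcm_total"]


class TestSweep:
    def test_grid_and_single_record(self):
        rec = SequenceRecord("r", "ACGT" * 100, label=1)
        table = sweep_kl([rec], k_values=(1, 2), L_values=(50, 100))
        assert set(zip(table["k"], table["L"])) == {(1, 50), (1, 100),
                                                    (2, 50), (2, 100)}
        assert (table["n"] == 1).all() and (table["sd_H"] == 0).all()

    def test_planted_positives_have_higher_mean_h(self):
        ds = generate(SyntheticConfig(n_pos=40, n_neg=40,
                                      length_range=(240, 300), seed=5))
        table = sweep_kl(ds.records, k_values=(3,), L_values=(100,))
        mean = {row["class"]: row["mean_H"] for _, row in table.iterrows()}
        assert mean[1] > mean[0]
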