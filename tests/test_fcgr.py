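"""FCGR construction and the additive-signature variants."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import importlib

fcgr_mod = importlib.import_module("addsig.fcgr")
from addsig import (
    ContigSpec,
    DnaSequence,
    FcgrMatrix,
    InvalidSequenceError,
    additive_signature,
    assembled_signature,
    composite_signature,
    fcgr,
    fully_assembled_signature,
    kmer_set,
    kmer_to_cell,
)
from conftest import brute_kmer_counts, random_dna

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestKmerSet:
    @pytest.mark.parametrize(
        "s, k, expected",
        [
            (
                "AAAACCCCGGGGTTTT",
                3,
                {"AAA", "AAC", "ACC", "CCC", "CCG", "CGG", "GGG", "GGT", "GTT", "TTT"},
            ),
            ("AAAA", 3, {"AAA"}),
            ("ACGT", 5, set()),
        ],
    )
    def test_examples(self, s, k, expected):
        assert kmer_set(s, k).members == frozenset(expected)

    def test_rejects_non_acgt(self):
        with pytest.raises(InvalidSequenceError):
            kmer_set("ACGN", 2)

    @settings(derandomize=True, max_examples=50)
    @given(dna, st.integers(1, 4))
    def test_matches_substring_scan(self, s, k):
        assert kmer_set(s, k).members == frozenset(brute_kmer_counts(s, k))


class TestKmerToCell:
    def test_quadrants_follow_corner_convention(self):
        # A=(0,0) bottom-left, C=(0,1) top-left, G=(1,1) top-right, T=(1,0) bottom-right
        assert kmer_to_cell("A") == (1, 0)
        assert kmer_to_cell("C") == (0, 0)
        assert kmer_to_cell("G") == (0, 1)
        assert kmer_to_cell("T") == (1, 1)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_bijective_over_all_kmers(self, k):
        from itertools import product

        cells = {kmer_to_cell("".join(p)) for p in product("ACGT", repeat=k)}
        assert len(cells) == 4**k

    def test_matches_geometric_cgr_walk(self, rng):
        """Cell arithmetic equals locating the exact CGR midpoint walk endpoint."""
        corners = {"A": (0, 0), "C": (0, 1), "G": (1, 1), "T": (1, 0)}
        for _ in range(50):
            k = int(rng.integers(1, 5))
            kmer = random_dna(rng, k)
            x, y = Fraction(1, 2), Fraction(1, 2)
            for ch in kmer:
                cx, cy = corners[ch]
                x = (x + cx) / 2
                y = (y + cy) / 2
            side = 2**k
            col = int(x * side)
            row = side - 1 - int(y * side)
            assert kmer_to_cell(kmer) == (row, col)


class TestFcgr:
    def test_worked_example_totals(self):
        F = fcgr("AAAACCCCGGGGTTTT", 3)
        assert F.total == 14
        assert F.support == 10

    def test_single_letter_sequence(self):
        F = fcgr("AAAA", 1)
        assert F.counts[kmer_to_cell("A")] == 4
        assert F.total == 4
        assert F.support == 1

    def test_counts_match_substring_scan(self, rng):
        for _ in range(50):
            s = random_dna(rng, int(rng.integers(0, 201)))
            k = int(rng.integers(1, 5))
            F = fcgr(s, k)
            oracle = brute_kmer_counts(s, k)
            assert F.support == len(oracle)
            for w, n in oracle.items():
                assert F.counts[kmer_to_cell(w)] == n

    @settings(derandomize=True, max_examples=50)
    @given(dna, st.integers(1, 4))
    def test_count_conservation(self, s, k):
        assert fcgr(s, k).total == max(0, len(s) - k + 1)

    @settings(derandomize=True, max_examples=30)
    @given(dna, dna, st.integers(2, 4))
    def test_quasi_homomorphism(self, s, t, k):
        """FCGR(st) - FCGR(s) - FCGR(t) is the non-negative junction-k-mer excess, <= k-1."""
        joint = fcgr(s + t, k)
        parts = fcgr(s, k) + fcgr(t, k)
        diff = joint.counts - parts.counts
        assert np.all(diff >= 0)
        assert diff.sum() <= k - 1

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            fcgr("ACGT", 0)
        with pytest.raises(ValueError):
            fcgr("ACGT", 13)


class TestAdditiveSignature:
    def test_contig_set_support(self):
        S = additive_signature(["AAAA", "CCCC", "GGGG", "TTTT"], 3)
        assert S.support == 4

    def test_singleton_equals_fcgr(self):
        s = "ACGTACGTAC"
        assert np.array_equal(additive_signature([s], 3).counts, fcgr(s, 3).counts)

    def test_three_homopolymers(self):
        S = additive_signature(["AAAAA", "CCCCC", "GGGGG"], 3)
        assert S.support == 3
        assert S.total == 9

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            additive_signature([], 3)

    def test_additivity_commutes_with_union(self, rng):
        S = [random_dna(rng, 30) for _ in range(3)]
        T = [random_dna(rng, 30) for _ in range(2)]
        both = additive_signature(S + T, 3)
        split = additive_signature(S, 3) + additive_signature(T, 3)
        assert np.array_equal(both.counts, split.counts)

    def test_support_identity_with_set_union_oracle(self, rng):
        for _ in range(20):
            S = [random_dna(rng, int(rng.integers(5, 60))) for _ in range(int(rng.integers(1, 5)))]
            k = int(rng.integers(1, 5))
            union = set().union(*(brute_kmer_counts(s, k).keys() for s in S))
            assert additive_signature(S, k).support == len(union)


class TestCompositeSignature:
    def test_zero_matrix_is_identity(self):
        F = fcgr("ACGTACGT", 2)
        Z = FcgrMatrix.zeros(2)
        assert np.array_equal(composite_signature([F, Z]).counts, F.counts)

    def test_support_subadditive(self, rng):
        for _ in range(50):
            s1, s2 = random_dna(rng, 40), random_dna(rng, 40)
            F1, F2 = fcgr(s1, 3), fcgr(s2, 3)
            comp = composite_signature([F1, F2])
            assert comp.support <= F1.support + F2.support
            union = set(brute_kmer_counts(s1, 3)) | set(brute_kmer_counts(s2, 3))
            assert comp.support == len(union)

    def test_weighted_sum(self):
        F = fcgr("AAAA", 2)
        W = composite_signature([F, F], weights=[1.0, 2.0])
        assert np.array_equal(W.counts, 3 * F.counts)

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            composite_signature([fcgr("ACGT", 2), fcgr("ACGT", 3)])


class TestFullyAssembled:
    def test_partition_discards_short_tail(self):
        # contigs {AAAAA, CCCCC, GGGGG}; remainder TTT discarded
        sig = fully_assembled_signature("AAAAACCCCCGGGGGTTT", n=5, k=3)
        expected = additive_signature(["AAAAA", "CCCCC", "GGGGG"], 3)
        assert np.array_equal(sig.counts, expected.counts)

    def test_equals_additive_of_partition(self):
        sig = fully_assembled_signature("AAAACCCCGGGGTTTT", n=4, k=3)
        expected = additive_signature(["AAAA", "CCCC", "GGGG", "TTTT"], 3)
        assert np.array_equal(sig.counts, expected.counts)

    @pytest.mark.parametrize("k", [2, 3])
    def test_exact_partition_totals(self, rng, k):
        s = random_dna(rng, 16)
        sig = fully_assembled_signature(s, n=4, k=k)
        assert sig.total == 4 * (4 - k + 1)

    def test_deterministic(self, rng):
        s = random_dna(rng, 101)
        a = fully_assembled_signature(s, n=10, k=3)
        b = fully_assembled_signature(s, n=10, k=3)
        assert np.array_equal(a.counts, b.counts)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fully_assembled_signature("ACGT", n=10, k=2)


class TestAssembled:
    def test_coverage_counts(self):
        spec_1pct = ContigSpec(n=300, t=0.01)
        spec_5pct = ContigSpec(n=300, t=0.05)
        assert spec_1pct.resolve_count(150_000) == 5
        assert spec_5pct.resolve_count(150_000) == 25

    def test_stubbed_sampler_totals(self, monkeypatch):
        # force contigs {AAACC, CCCGG, CCCGG}: starts 2, 7, 7 (0-based)
        monkeypatch.setattr(
            fcgr_mod, "_draw_starts", lambda rng, count, hi: np.array([2, 7, 7])
        )
        sig = assembled_signature(
            "AAAAACCCCCGGGGGTTT", ContigSpec(n=5, r=3), seed=0, k=3
        )
        assert sig.total == 9  # 3 contigs x (5 - 3 + 1) k-mer occurrences
        expected = additive_signature(["AAACC", "CCCGG", "CCCGG"], 3)
        assert np.array_equal(sig.counts, expected.counts)

    def test_reproducible_per_seed(self, rng):
        s = random_dna(rng, 2000)
        spec = ContigSpec(n=50, r=10)
        a = assembled_signature(s, spec, seed=5, k=4)
        b = assembled_signature(s, spec, seed=5, k=4)
        c = assembled_signature(s, spec, seed=6, k=4)
        assert np.array_equal(a.counts, b.counts)
        assert a.total == c.total  # same amount of sequence read either way

    def test_contigs_are_windows_of_s(self, rng):
        """Every sampled contig's k-mers occur in s at the sampled positions."""
        s = random_dna(rng, 500)
        sig = assembled_signature(s, ContigSpec(n=40, r=6), seed=1, k=3)
        full = fcgr(s, 3)
        assert np.all((sig.counts > 0) <= (full.counts > 0))

    def test_variable_length_mode(self, rng):
        s = random_dna(rng, 3000)
        spec = ContigSpec(n=100, r=20, mode="assembled_variable", sigma=40.0)
        sig = assembled_signature(s, spec, seed=3, k=4)
        assert sig.total > 0
        full = fcgr(s, 4)
        assert np.all((sig.counts > 0) <= (full.counts > 0))

    def test_zero_contigs_rejected(self):
        with pytest.raises(ValueError):
            assembled_signature("ACGT" * 100, ContigSpec(n=50, t=0.0001), seed=0, k=3)


class TestDnaSequence:
    def test_case_folding(self):
        assert DnaSequence("acgt").residues == "ACGT"

    def test_rejects_other_characters(self):
        with pytest.raises(InvalidSequenceError):
            DnaSequence("ACGN")
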