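import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribodelim.dist import DistanceMatrix
from ribodelim.kmer import (KmerProfile, ReadFilterParams, binary_distance,
                            canonical, cluster_with_stability, distance_matrix,
                            filter_reads, kmer_set, reverse_complement,
                            shannon_entropy)


def set_algebra_oracle(A, B, metric):
    """Straight-from-the-definition distances via python set ops."""
    n11 = len(A & B)
    n10, n01 = len(A - B), len(B - A)
    if metric == "kulczynski":
        return 1 - 0.5 * (n11 / (n11 + n10) + n11 / (n11 + n01))
    ochiai = 1 - n11 / math.sqrt((n11 + n10) * (n11 + n01))
    return ochiai if metric == "ochiai" else math.sqrt(2 * ochiai)


def profile(kmers, k=3, sid="s"):
    return KmerProfile(sid, frozenset(canonical(w) for w in kmers), k)


class TestReadFilter:
    def test_homopolymer_discarded(self):
        assert filter_reads(["A" * 100]) == []

    def test_short_complex_read_discarded(self):
        read = ("ACGT" * 23)[:89]
        assert filter_reads([read]) == []

    def test_two_letter_read_entropy_one_discarded(self):
        # frequencies (0.5, 0.5, 0, 0): H = 1 bit < 1.5
        read = "AC" * 50
        assert shannon_entropy(read) == pytest.approx(1.0)
        assert filter_reads([read]) == []

    def test_balanced_read_retained(self):
        read = "ACGT" * 25
        assert shannon_entropy(read) == pytest.approx(2.0)
        assert filter_reads([read]) == [read]

    def test_params_validated(self):
        with pytest.raises(ValueError):
            ReadFilterParams(min_len=10, k=21)


class TestKmerSet:
    def test_hand_canonicalization(self):
        p = kmer_set(["ACGTA"], k=3)
        assert p.kmers == {"ACG", "GTA"}  # CGT canonicalizes onto ACG

    def test_n_windows_skipped(self):
        assert kmer_set(["ANGT"], k=3).kmers == frozenset()

    def test_short_read_skipped(self):
        assert kmer_set(["ACG"], k=5).kmers == frozenset()

    def test_palindrome_is_own_canonical(self):
        assert canonical("ACGT") == "ACGT" == reverse_complement("ACGT")

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=25))
    def test_canonical_idempotent_and_strand_neutral(self, w):
        assert canonical(canonical(w)) == canonical(w)
        assert canonical(reverse_complement(w)) == canonical(w)


class TestBinaryDistance:
    def test_identical_sets_zero(self):
        p = profile(["AAA", "AAC", "CCC"])
        for m in ("kulczynski", "ochiai", "chord"):
            assert binary_distance(p, p, m) == 0.0

    def test_hand_example(self):
        a = profile(["AAA", "AAC", "ACC"], sid="a")
        b = profile(["AAC", "ACC", "CCA"], sid="b")
        assert binary_distance(a, b, "kulczynski") == pytest.approx(1 / 3)
        assert binary_distance(a, b, "ochiai") == pytest.approx(1 / 3)
        assert binary_distance(a, b, "chord") == pytest.approx(math.sqrt(2 / 3))

    def test_disjoint_sets(self):
        a = profile(["AAA"], sid="a")
        b = profile(["CCC"], sid="b")
        assert binary_distance(a, b, "kulczynski") == 1.0
        assert binary_distance(a, b, "ochiai") == 1.0
        assert binary_distance(a, b, "chord") == pytest.approx(math.sqrt(2))

    def test_chord_ochiai_relation_and_bounds(self, rng):
        pool = ["".join(x) for x in
                np.array(list("ACGT"))[rng.integers(0, 4, (60, 5))]]
        pool = [canonical(w) for w in pool]
        for _ in range(50):
            A = frozenset(rng.choice(pool, rng.integers(1, 30)))
            B = frozenset(rng.choice(pool, rng.integers(1, 30)))
            pa, pb = KmerProfile("a", A, 5), KmerProfile("b", B, 5)
            och = binary_distance(pa, pb, "ochiai")
            cho = binary_distance(pa, pb, "chord")
            kul = binary_distance(pa, pb, "kulczynski")
            assert abs(cho - math.sqrt(2 * och)) < 1e-12
            assert 0 <= kul <= 1 and 0 <= och <= 1 and cho <= math.sqrt(2) + 1e-12

    def test_shrinking_intersection_never_decreases(self, rng):
        base = profile([f"AA{c}" for c in "ACGT"] + ["CCA", "CCG"], sid="a")
        other = profile(["AAA", "AAC", "CCA", "GGA"], sid="b")
        for metric in ("kulczynski", "ochiai", "chord"):
            d0 = binary_distance(base, other, metric)
            shared = sorted(base.kmers & other.kmers)
            smaller = KmerProfile("a2", base.kmers - {shared[0]}, 3)
            assert binary_distance(smaller, other, metric) >= d0 - 1e-12

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            binary_distance(KmerProfile("a", frozenset(), 3),
                            profile(["AAA"]), "kulczynski")

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            binary_distance(profile(["AAA"]), KmerProfile("b", {"AAAA"}, 4))


class TestDistanceMatrix:
    def test_identical_profiles_zero_matrix(self):
        ps = [profile(["AAA", "AAC"], sid=f"s{i}") for i in range(4)]
        assert not distance_matrix(ps).values.any()

    def test_matches_double_loop_oracle(self, rng):
        pool = [canonical("".join(x)) for x in
                np.array(list("ACGT"))[rng.integers(0, 4, (200, 7))]]
        ps = [KmerProfile(f"s{i}", frozenset(rng.choice(pool, 40)), 7)
              for i in range(20)]
        for metric in ("kulczynski", "ochiai", "chord"):
            d = distance_matrix(ps, metric)
            for i in range(20):
                for j in range(i + 1, 20):
                    want = set_algebra_oracle(set(ps[i].kmers), set(ps[j].kmers), metric)
                    assert abs(d.values[i, j] - want) < 1e-12

    def test_permutation_equivariance(self, rng):
        pool = [canonical("".join(x)) for x in
                np.array(list("ACGT"))[rng.integers(0, 4, (50, 5))]]
        ps = [KmerProfile(f"s{i}", frozenset(rng.choice(pool, 15)), 5)
              for i in range(5)]
        d1 = distance_matrix(ps)
        d2 = distance_matrix(ps[::-1])
        for a in d1.ids:
            for b in d1.ids:
                if a != b:
                    assert d1.between(a, b) == d2.between(a, b)


class TestClusterStability:
    def test_two_separated_blobs_fully_stable(self):
        n = 10
        d = np.full((2 * n, 2 * n), 0.9)
        d[:n, :n] = 0.05
        d[n:, n:] = 0.05
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(2 * n)], d)
        rep = cluster_with_stability(dm, 2, n_boot=50, seed=0)
        assert rep.min_stability() == pytest.approx(1.0)
        labels = set(rep.assignment[f"s{i}"] for i in range(n))
        assert len(labels) == 1

    def test_random_distances_unstable(self, rng):
        n = 30
        vals = rng.uniform(0.2, 1.0, (n, n))
        d = (vals + vals.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        rep = cluster_with_stability(dm, 2, n_boot=50, seed=1)
        assert np.mean(list(rep.stability.values())) < 0.7

    def test_k_bounds_enforced(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        dm = DistanceMatrix(["a", "b"], d)
        with pytest.raises(ValueError):
            cluster_with_stability(dm, 1)
        with pytest.raises(ValueError):
            cluster_with_stability(dm, 3)
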