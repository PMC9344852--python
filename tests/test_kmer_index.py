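"""Unit and property tests for the k-mer pigeonhole index."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shepherd as sh
from shepherd.kmer_index import ConfigurationError, choose_k, decode_sequences

from conftest import brute_force_neighbors, mutate, random_sequences

dna = st.text(alphabet="ACGT", min_size=8, max_size=8)


class TestHamming:
    def test_identity_and_saturation(self):
        assert sh.hamming("ACGT", "ACGT") == 0
        assert sh.hamming("AAAA", "TTTT") == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sh.hamming("ACG", "ACGT")

    def test_matches_positionwise_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            a = "".join(rng.choice(list("ACGT"), 26))
            b = "".join(rng.choice(list("ACGT"), 26))
            oracle = sum(1 for x, y in zip(a, b) if x != y)
            assert sh.hamming(a, b) == oracle

    @given(dna, dna, st.integers(min_value=0, max_value=8))
    def test_cap_only_saturates_above_cap(self, a, b, cap):
        d = sh.hamming(a, b)
        capped = sh.hamming(a, b, cap=cap)
        if d <= cap:
            assert capped == d
        else:
            assert capped == cap + 1


class TestScheme:
    def test_even_partition(self):
        s = sh.make_scheme(8, 2, k=2)
        assert (s.p, s.r) == (4, 0)
        assert s.partition_bounds == ((0, 2), (2, 4), (4, 6), (6, 8))
        assert s.n_combinations == 6

    def test_remainder_partition(self):
        s = sh.make_scheme(26, 2, k=3)
        assert (s.p, s.r) == (9, 2)
        assert s.partition_bounds[-1] == (24, 26)
        assert s.n_combinations == 36

    def test_infeasible_epsilon(self):
        with pytest.raises(ConfigurationError):
            sh.make_scheme(4, 4)

    def test_auto_k_is_feasible(self):
        for l, eps in [(26, 1), (26, 2), (26, 3), (20, 2), (8, 2)]:
            k = choose_k(l, eps, 100_000)
            s = sh.make_scheme(l, eps, k=k)
            assert s.p - eps >= 1


class TestCombinationIds:
    def test_count_and_determinism(self):
        s = sh.make_scheme(8, 2, k=2)
        ids = sh.combination_ids("ACGTACGT", s)
        assert len(ids) == 6
        assert ids == sh.combination_ids("ACGTACGT", s)

    def test_alphabet_error(self):
        s = sh.make_scheme(8, 2, k=2)
        with pytest.raises(sh.kmer_index.AlphabetError):
            sh.combination_ids("ACGTACGN", s)

    def test_shared_id_iff_matching_partition_exhaustive(self):
        # l=4, k=2, eps=1: two sequences share an ID iff they agree on at
        # least one of the two partitions; exhaustive over all pairs of a
        # 32-sequence sample of the 256-sequence space (plus all-equal pairs)
        s = sh.make_scheme(4, 1, k=2)
        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
        ids = {q: set(sh.combination_ids(q, s)) for q in seqs}
        for a in seqs[::8]:
            for b in seqs:
                share = bool(ids[a] & ids[b])
                agree = a[:2] == b[:2] or a[2:] == b[2:]
                assert share == agree


class TestIndexAndNeighborhoods:
    def test_single_sequence_index(self):
        reads = sh.ReadSet(["ACGTACGT"], [5], 8)
        s = sh.make_scheme(8, 2, k=2)
        index = sh.build_index(reads, s)
        assert len(index.table) == 6
        assert all(v == [0] for v in index.table.values())
        # self-exclusion on query
        assert sh.kmer_neighborhood("ACGTACGT", index) == set()

    def test_id_count_conservation(self, rng):
        seqs = random_sequences(rng, 200, 26)
        reads = sh.ReadSet(seqs, np.ones(200, dtype=int), 26)
        s = sh.make_scheme(26, 2, k=3)
        index = sh.build_index(reads, s)
        appearances = np.zeros(200, dtype=int)
        for bucket in index.table.values():
            for i in bucket:
                appearances[i] += 1
        assert (appearances == s.n_combinations).all()

    def test_membership_matches_per_sequence_recomputation(self, rng):
        seqs = random_sequences(rng, 200, 26)
        reads = sh.ReadSet(seqs, np.ones(200, dtype=int), 26)
        s = sh.make_scheme(26, 2, k=3)
        index = sh.build_index(reads, s)
        for i, seq in enumerate(seqs):
            for cid in sh.combination_ids(seq, s):
                assert i in index.table[cid]

    def test_pairs_within_epsilon_share_enough_kmers(self, rng):
        # toy in the style of the worked l=8 example: every pair within
        # Hamming 2 shares at least p - eps = 2 partition combinations
        base = "ACGTACGT"
        seqs = [base, mutate(rng, base, 1), mutate(rng, base, 2), mutate(rng, base, 3)]
        seqs = list(dict.fromkeys(seqs))
        s = sh.make_scheme(8, 2, k=2)
        ids = {q: set(sh.combination_ids(q, s)) for q in seqs}
        for a in seqs:
            for b in seqs:
                if a != b and sh.hamming(a, b) <= 2:
                    assert len(ids[a] & ids[b]) >= 1

    def test_kmer_neighborhood_superset_and_distance_bound(self, rng):
        # planted mutants: k-mer neighborhood must contain every true
        # epsilon-neighbor; with r=0 no member may exceed distance k*eps
        base_seqs = random_sequences(rng, 100, 24)
        seqs = set(base_seqs)
        for b in base_seqs[:30]:
            seqs.add(mutate(rng, b, int(rng.integers(1, 3))))
        seqs = sorted(seqs)
        reads = sh.ReadSet(seqs, np.ones(len(seqs), dtype=int), 24)
        s = sh.make_scheme(24, 2, k=3)  # divides evenly: r = 0
        assert s.r == 0
        index = sh.build_index(reads, s)
        for i in range(0, len(seqs), 7):
            hood = sh.kmer_neighborhood(i, index)
            truth = {j for j, _ in brute_force_neighbors(reads, i, 2)}
            assert truth <= hood
            for j in hood:
                assert sh.hamming(seqs[i], seqs[j]) <= s.k * s.epsilon

    def test_neighborhood_monotone_in_epsilon(self, rng):
        seqs = random_sequences(rng, 80, 26)
        seqs += [mutate(rng, s, 2) for s in seqs[:20]]
        seqs = sorted(set(seqs))
        reads = sh.ReadSet(seqs, np.ones(len(seqs), dtype=int), 26)
        prev = None
        for eps in (1, 2, 3):
            s = sh.make_scheme(26, eps, k=3)
            index = sh.build_index(reads, s)
            hoods = [frozenset(sh.kmer_neighborhood(i, index)) for i in range(len(seqs))]
            if prev is not None:
                assert all(a <= b for a, b in zip(prev, hoods))
            prev = hoods

    def test_epsilon_neighborhood_equals_brute_force(self, rng):
        # pigeonhole soundness at moderate scale, planted mutants included
        for seed_shift in range(5):
            local = np.random.default_rng(500 + seed_shift)
            seqs = set(random_sequences(local, 300, 26))
            planted = sorted(seqs)[:50]
            for b in planted:
                seqs.add(mutate(local, b, int(local.integers(1, 4))))
            seqs = sorted(seqs)
            counts = local.integers(1, 100, size=len(seqs))
            reads = sh.ReadSet(seqs, counts, 26)
            s = sh.make_scheme(26, 2, n_sequences=len(seqs))
            index = sh.build_index(reads, s)
            for i in range(0, len(seqs), 11):
                got = sorted(sh.epsilon_neighborhood(i, index))
                expect = sorted(brute_force_neighbors(reads, i, 2))
                assert got == expect

    def test_boundary_distance_inclusion(self, rng):
        base = random_sequences(rng, 1, 26)[0]
        at_eps = mutate(rng, base, 2)
        beyond = mutate(rng, base, 3)
        seqs = sorted({base, at_eps, beyond})
        reads = sh.ReadSet(seqs, np.ones(len(seqs), dtype=int), 26)
        s = sh.make_scheme(26, 2, k=3)
        index = sh.build_index(reads, s)
        hood = dict(sh.epsilon_neighborhood(base, index))
        assert hood.get(seqs.index(at_eps)) == 2
        assert seqs.index(beyond) not in hood

    def test_sorted_by_distance_then_count(self, rng):
        base = random_sequences(rng, 1, 26)[0]
        m1a, m1b, m2 = mutate(rng, base, 1), mutate(rng, base, 1), mutate(rng, base, 2)
        pairs = [(base, 10), (m1a, 3), (m1b, 7), (m2, 100)]
        reads = sh.ReadSet.from_pairs(pairs, length=26)
        s = sh.make_scheme(26, 2, k=3)
        index = sh.build_index(reads, s)
        hood = sh.epsilon_neighborhood(base, index)
        dists = [d for _, d in hood]
        assert dists == sorted(dists)
        counts = [int(reads.counts[i]) for (i, d) in hood if d == 1]
        assert counts == sorted(counts, reverse=True)


def test_encode_decode_roundtrip(rng):
    seqs = random_sequences(rng, 50, 26)
    enc = sh.kmer_index.encode_sequences(seqs, 26)
    assert decode_sequences(enc) == seqs
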