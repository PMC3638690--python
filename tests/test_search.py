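"""Candidate generation, block-aligned extension, and the full engine."""

import numpy as np
import pytest

from uniqoligo import (
    EstDatabase,
    OligoOccurrence,
    Scheme,
    SearchParams,
    brute_force,
    build_index,
    candidate_pairs,
    derive_params,
    extend_and_verify,
    find_nonunique,
    generate_db,
    hamming,
)


def _params(l, d, scheme):
    return derive_params(l, d, scheme)


class TestCandidatePairs:
    def test_singleton_buckets_yield_nothing(self):
        db = EstDatabase(records=[("s1", "ACGT")])
        p = _params(4, 0, Scheme.EXACT)  # k=1, q=4, m=0
        assert list(candidate_pairs(build_index(db, p.q), p)) == []

    def test_within_bucket_pair_count(self):
        db = EstDatabase(records=[("s1", "AAAAAA")])  # three AAAA windows
        p = _params(4, 0, Scheme.EXACT)
        pairs = list(candidate_pairs(build_index(db, p.q), p))
        assert len(pairs) == 3  # C(3,2)
        assert all(a < b for a, b in pairs)

    def test_mutant_cross_pass_yields_pair_once(self):
        db = EstDatabase(records=[("s1", "AAAA"), ("s2", "AACA")])
        p = _params(4, 1, Scheme.ONE_MISMATCH)  # k=1, q=4, m=1
        pairs = list(candidate_pairs(build_index(db, p.q), p))
        assert pairs == [(OligoOccurrence(0, 0), OligoOccurrence(1, 0))]

    def test_q_mismatch_rejected(self):
        db = EstDatabase(records=[("s1", "ACGT")])
        p = _params(4, 0, Scheme.EXACT)
        with pytest.raises(ValueError):
            list(candidate_pairs(build_index(db, 3), p))


class TestExtendAndVerify:
    def test_identical_sequences_verify_at_every_block(self):
        rng = np.random.default_rng(0)
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 28)])
        db = EstDatabase(records=[("s1", s), ("s2", s)])
        for scheme in Scheme:
            p = _params(28, 6, scheme)
            for j in range(p.k):
                pair = (OligoOccurrence(0, j * p.q), OligoOccurrence(1, j * p.q))
                assert ((0, 0), (1, 0)) in extend_and_verify(pair, db, p)

    def test_filter_superset_is_cut_by_verification(self):
        # share an exact 7-mer seed but differ at 7 positions > d=6
        base = "ACGTACG" * 4
        other = "TGCATGC" * 3 + "ACGTACG"  # block 3 identical, 21 mismatches
        db = EstDatabase(records=[("s1", base), ("s2", other)])
        p = _params(28, 6, Scheme.ONE_MISMATCH)
        pair = (OligoOccurrence(0, 21), OligoOccurrence(1, 21))
        assert extend_and_verify(pair, db, p) == []

    def test_planted_six_substitutions_recovered_via_clean_block(self):
        rng = np.random.default_rng(1)
        s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 28)])
        # six substitutions, none inside block 2 ([14, 21))
        positions = [0, 3, 8, 22, 25, 27]
        s2 = list(s1)
        for pos in positions:
            s2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[pos]]
        s2 = "".join(s2)
        assert hamming(s1, s2) == 6
        db = EstDatabase(records=[("s1", s1), ("s2", s2)])
        p = _params(28, 6, Scheme.ONE_MISMATCH)
        pair = (OligoOccurrence(0, 14), OligoOccurrence(1, 14))  # block-2 seeds
        assert (((0, 0), (1, 0))) in extend_and_verify(pair, db, p)

    def test_out_of_bounds_candidates_skipped_silently(self):
        db = EstDatabase(records=[("s1", "ACGTACGT"), ("s2", "ACGTACGT")])
        p = _params(8, 1, Scheme.ONE_MISMATCH)  # k=1, q=8
        pair = (OligoOccurrence(0, 0), OligoOccurrence(1, 0))
        assert extend_and_verify(pair, db, p) == [((0, 0), (1, 0))]


class TestFindNonunique:
    def test_single_sequence_all_unique_under_cross_est_policy(self):
        db = EstDatabase(records=[("s1", "ACGTACGTACGT")])
        p = _params(4, 0, Scheme.EXACT)
        res = find_nonunique(db, p)
        assert res.n_nonunique == 0
        assert res.n_unique == 9

    def test_duplicate_sequence_kills_every_oligo(self):
        seq = "ACGTTGCAACGT"
        db = EstDatabase(records=[("a", seq), ("b", seq)])
        for scheme in Scheme:
            res = find_nonunique(db, _params(6, 1, scheme))
            assert res.n_unique == 0
            assert all(len(s) == len(seq) - 5 for s in res.nonunique)

    def test_within_est_policy_marks_internal_repeats(self):
        db = EstDatabase(records=[("s1", "ACGTACGT")])
        p = _params(4, 0, Scheme.EXACT)
        strict = find_nonunique(db, p, within_est=True)
        # ACGT occurs at 0 and 4 within the same EST
        assert {0, 4} <= strict.nonunique[0]
        lax = find_nonunique(db, p, within_est=False)
        assert lax.n_nonunique == 0

    def test_partition_of_clean_windows(self, random_db):
        p = _params(16, 2, Scheme.ONE_MISMATCH)
        res = find_nonunique(random_db, p)
        for i, (_, seq) in enumerate(random_db):
            nwin = len(seq) - p.l + 1
            uniq_starts = {s for s, _ in res.unique_oligos[i]}
            assert uniq_starts.isdisjoint(res.nonunique[i])
            assert uniq_starts | res.nonunique[i] == set(range(nwin))
        for i in range(len(random_db)):
            for start, oligo in res.unique_oligos[i]:
                assert len(oligo) == p.l and set(oligo) <= set("ACGT")

    def test_monotone_in_d(self):
        db = generate_db(6, (60, 90), seed=11)
        marks_by_d = []
        for d in range(4):
            res = find_nonunique(db, _params(10, d, Scheme.ONE_MISMATCH))
            marks_by_d.append(res.marks())
        for lo, hi in zip(marks_by_d, marks_by_d[1:]):
            for a, b in zip(lo, hi):
                assert a <= b  # non-unique set only grows with d

    def test_order_independence(self, random_db):
        p = _params(12, 2, Scheme.TWO_MISMATCH)
        fwd = find_nonunique(random_db, p)
        perm = list(range(len(random_db)))[::-1]
        shuffled = EstDatabase(records=[random_db.records[i] for i in perm])
        rev = find_nonunique(shuffled, p)
        for new, old in enumerate(perm):
            assert rev.nonunique[new] == fwd.nonunique[old]

    def test_oversized_l_warns(self):
        db = EstDatabase(records=[("s1", "ACGT")])
        p = SearchParams(l=10, d=0, scheme=Scheme.EXACT, q=1, k=1, m=0)
        with pytest.warns(UserWarning, match="no windows"):
            res = find_nonunique(db, p)
        assert res.n_nonunique == 0 and res.n_unique == 0

    def test_ambiguous_bases_never_reported(self):
        db = EstDatabase(records=[("s1", "ACGTNACGT"), ("s2", "GGGGGGGGG")])
        p = _params(4, 0, Scheme.EXACT)
        res = find_nonunique(db, p)
        starts = {s for s, _ in res.unique_oligos[0]} | res.nonunique[0]
        assert starts == {0, 5}  # windows touching N are excluded

    def test_degenerate_scheme_overmatching_is_cut_by_verification(self):
        """m=1 at d=0 over-generates candidates; HD verification restores d=0."""
        db = EstDatabase(records=[("a", "AAAAT"), ("b", "AAAAC")])
        p = _params(5, 0, Scheme.ONE_MISMATCH)  # k=1, q=5, m=1 but d=0
        assert (p.k, p.m) == (1, 1)
        res = find_nonunique(db, p)
        assert res.n_nonunique == 0  # HD=1 > d=0
        assert res.same_marks(brute_force(db, 5, 0))
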