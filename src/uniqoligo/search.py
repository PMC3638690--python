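"""Phase two: seed-pair generation, block-aligned extension, verification.

Candidate q-mer occurrence pairs come from two passes over the index:

* within each bucket, every unordered pair of distinct occurrences
  (identical seeds);
* for schemes with per-block budget m >= 1, every cross-bucket pair
  between bucket c and each occupied mutant bucket c' in the m-mutant
  list of c with c' > c (each unordered bucket pair visited once).

Each seed pair is then extended to the aligned l-mer pairs that contain the
seeds at the same block offset: for block index j the candidate l-mer
starts are ``p - j*q`` on both sides.  The pigeonhole theorems guarantee
the matching seed occupies the *same* block index in both l-mers, so
block-aligned extension is complete; candidates are finally verified by an
exact Hamming-distance test against d, so the filter never over-marks.
Verification makes the engine correct even for degenerate parameter
choices where the seed filter over-matches (e.g. m=1 at d=0).

Both members of every verified cross-sequence pair are marked non-unique.
Same-sequence approximate repeats do not disqualify an oligo by default
(uniqueness is defined against *other* ESTs); ``within_est=True`` enables
the stricter policy.  Marking is idempotent, so rediscovering a pair via
several block indices or seed pairs is harmless and the output is
independent of enumeration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core import EstDatabase, OligoOccurrence, SearchParams, block_starts
from .encoding import clean_windows, encode_sequence, mutant_codes
from .index import KmerIndex, build_index

__all__ = [
    "UniquenessResult",
    "candidate_pairs",
    "extend_and_verify",
    "find_nonunique",
]

# pairs accumulated before one vectorised extend+verify sweep
_CHUNK = 1 << 16


@dataclass
class UniquenessResult:
    """Outcome of a uniqueness search.

    ``nonunique[i]`` is the set of 0-based l-mer start positions in sequence
    i marked non-unique; ``unique_oligos[i]`` is the sorted list of
    ``(start, oligo_string)`` for every clean l-window never marked.  The
    two partition the clean l-windows of each sequence.
    """

    params: "SearchParams | None"
    nonunique: list[set[int]]
    unique_oligos: list[list[tuple[int, str]]]

    @property
    def n_nonunique(self) -> int:
        """Marked window positions summed over sequences."""
        return sum(len(s) for s in self.nonunique)

    @property
    def n_unique(self) -> int:
        return sum(len(u) for u in self.unique_oligos)

    def marks(self) -> tuple[frozenset[int], ...]:
        """Hashable per-sequence mark sets, for equality comparisons."""
        return tuple(frozenset(s) for s in self.nonunique)

    def same_marks(self, other: "UniquenessResult") -> bool:
        return self.marks() == other.marks()


def _cross_partners(
    code: int, q: int, m: int, occupied: "set[int]"
) -> list[int]:
    """Occupied mutant buckets c' > code, each unordered pair once."""
    if m == 0:
        return []
    return [c2 for c2 in mutant_codes(code, q, m) if c2 > code and c2 in occupied]


def candidate_pairs(
    index: KmerIndex, params: SearchParams
) -> Iterator[tuple[OligoOccurrence, OligoOccurrence]]:
    """Stream of candidate seed-occurrence pairs, each yielded exactly once.

    Within-bucket pairs are unordered pairs of distinct occurrences;
    cross-bucket pairs (m >= 1) pair every occurrence of bucket c with
    every occurrence of each occupied m-mutant bucket c' > c.
    """
    if index.q != params.q:
        raise ValueError(f"index q={index.q} != params q={params.q}")
    occupied = set(index.buckets)
    for code in sorted(occupied):
        occs = index.buckets[code]
        for a in range(len(occs)):
            for b in range(a + 1, len(occs)):
                yield occs[a], occs[b]
        for code2 in _cross_partners(code, params.q, params.m, occupied):
            for occ1 in occs:
                for occ2 in index.buckets[code2]:
                    yield occ1, occ2


def extend_and_verify(
    pair: tuple[OligoOccurrence, OligoOccurrence],
    db: EstDatabase,
    params: SearchParams,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Extend one seed pair to verified aligned l-mer pairs.

    For each block index j, the candidate l-mer starts are
    ``(p1 - j*q, p2 - j*q)``; a candidate survives if both starts are in
    bounds, both l-windows are clean, and the two l-mers are within
    Hamming distance d.  Reference (string-space) implementation; the
    engine's bulk path is vectorised but must agree.
    """
    (s1, p1), (s2, p2) = pair
    seqs = db.sequences
    out = []
    seen: set[tuple[int, int]] = set()
    for off in block_starts(params):
        a1, a2 = p1 - off, p2 - off
        if a1 < 0 or a2 < 0:
            continue
        if a1 + params.l > len(seqs[s1]) or a2 + params.l > len(seqs[s2]):
            continue
        if (a1, a2) in seen:  # repeated block offset alignment
            continue
        seen.add((a1, a2))
        w1 = seqs[s1][a1 : a1 + params.l]
        w2 = seqs[s2][a2 : a2 + params.l]
        if any(c not in "ACGT" for c in w1) or any(c not in "ACGT" for c in w2):
            continue
        if sum(x != y for x, y in zip(w1, w2)) <= params.d:
            out.append(((s1, a1), (s2, a2)))
    return out


class _Extender:
    """Vectorised extend+verify over flat pair arrays.

    Holds the concatenated 2-bit code array of the whole database plus
    per-sequence offsets, clean-l-window masks and the mark bitmaps.
    """

    def __init__(self, db: EstDatabase, params: SearchParams, within_est: bool):
        self.params = params
        self.within_est = within_est
        self.offsets = block_starts(params)
        seq_codes = [encode_sequence(s) for s in db.sequences]
        lens = np.array([len(c) for c in seq_codes], dtype=np.int64)
        self.seq_len = lens
        self.cat = (
            np.concatenate(seq_codes) if seq_codes else np.empty(0, np.int8)
        )
        self.cat_off = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
        l = params.l
        self.nwin = np.maximum(lens - l + 1, 0)
        self.win_off = np.concatenate([[0], np.cumsum(self.nwin)]).astype(
            np.int64
        )
        cleans = [clean_windows(c, l) for c in seq_codes]
        self.clean_l = (
            np.concatenate(cleans) if cleans else np.empty(0, bool)
        )
        self.marks = np.zeros(len(self.clean_l), dtype=bool)
        self._lrange = np.arange(l, dtype=np.int64)

    def process(
        self,
        s1: np.ndarray,
        p1: np.ndarray,
        s2: np.ndarray,
        p2: np.ndarray,
    ) -> None:
        """Extend seed pairs across all block offsets; mark verified pairs."""
        l, d, q = self.params.l, self.params.d, self.params.q
        if not self.within_est:
            keep = s1 != s2
            s1, p1, s2, p2 = s1[keep], p1[keep], s2[keep], p2[keep]
        if not len(s1):
            return
        for off in self.offsets:
            a1 = p1 - off
            a2 = p2 - off
            ok = (
                (a1 >= 0)
                & (a2 >= 0)
                & (a1 <= self.seq_len[s1] - l)
                & (a2 <= self.seq_len[s2] - l)
            )
            if self.within_est:
                ok &= (s1 != s2) | (a1 != a2)
            if not ok.any():
                continue
            t1, u1 = s1[ok], a1[ok]
            t2, u2 = s2[ok], a2[ok]
            w1 = self.win_off[t1] + u1
            w2 = self.win_off[t2] + u2
            clean = self.clean_l[w1] & self.clean_l[w2]
            # both already marked: verification cannot change the output
            todo = clean & ~(self.marks[w1] & self.marks[w2])
            if not todo.any():
                continue
            t1, u1, w1 = t1[todo], u1[todo], w1[todo]
            t2, u2, w2 = t2[todo], u2[todo], w2[todo]
            g1 = (self.cat_off[t1] + u1)[:, None] + self._lrange
            g2 = (self.cat_off[t2] + u2)[:, None] + self._lrange
            hd = np.count_nonzero(self.cat[g1] != self.cat[g2], axis=1)
            hit = hd <= d
            if hit.any():
                self.marks[w1[hit]] = True
                self.marks[w2[hit]] = True


def _mark_sets(ext: _Extender, num_seqs: int) -> list[set[int]]:
    out: list[set[int]] = []
    for i in range(num_seqs):
        lo, hi = ext.win_off[i], ext.win_off[i + 1]
        out.append(set(np.flatnonzero(ext.marks[lo:hi]).tolist()))
    return out


def result_from_marks(
    db: EstDatabase, params: "SearchParams | None", l: int,
    nonunique: list[set[int]],
) -> UniquenessResult:
    """Assemble a result: unique oligos are clean l-windows never marked."""
    uniques: list[list[tuple[int, str]]] = []
    for i, (_, seq) in enumerate(db):
        codes = encode_sequence(seq)
        clean = clean_windows(codes, l)
        marked = nonunique[i]
        uniques.append(
            [
                (int(p), seq[p : p + l])
                for p in np.flatnonzero(clean)
                if int(p) not in marked
            ]
        )
    return UniquenessResult(
        params=params, nonunique=nonunique, unique_oligos=uniques
    )


def find_nonunique(
    db: EstDatabase,
    params: SearchParams,
    within_est: bool = False,
    key_range: "tuple[int, int] | None" = None,
    index: "KmerIndex | None" = None,
) -> UniquenessResult:
    """Run the full two-phase search and report non-unique marks + uniques.

    Parameters
    ----------
    within_est : also disqualify oligos with approximate repeats in their
        own EST (default: only other ESTs count).
    key_range : half-open ``(lo, hi)`` code range restricting the *owning*
        buckets processed — the parallel driver's work unit.  Cross-bucket
        mutant pairs are owned by the lower key, so a worker still consults
        the whole index.  Mark sets only are meaningful for partial ranges.
    index : reuse a prebuilt index (must have ``q == params.q``).
    """
    if index is None:
        index = build_index(db, params.q)
    elif index.q != params.q:
        raise ValueError(f"index q={index.q} != params q={params.q}")

    longest = max((len(s) for s in db.sequences), default=0)
    if db.records and params.l > longest:
        warnings.warn(
            f"l={params.l} exceeds every sequence length; no windows exist",
            stacklevel=2,
        )

    ext = _Extender(db, params, within_est)
    occupied = set(index.buckets)
    keys = sorted(occupied)
    if key_range is not None:
        lo, hi = key_range
        keys = [c for c in keys if lo <= c < hi]

    buf1s: list[np.ndarray] = []
    buf1p: list[np.ndarray] = []
    buf2s: list[np.ndarray] = []
    buf2p: list[np.ndarray] = []
    buffered = 0

    def flush() -> None:
        nonlocal buffered
        if not buffered:
            return
        ext.process(
            np.concatenate(buf1s),
            np.concatenate(buf1p),
            np.concatenate(buf2s),
            np.concatenate(buf2p),
        )
        buf1s.clear(), buf1p.clear(), buf2s.clear(), buf2p.clear()
        buffered = 0

    def push(s1, p1, s2, p2) -> None:
        nonlocal buffered
        # split oversized batches so peak memory stays bounded
        for lo_ in range(0, len(s1), _CHUNK):
            sl = slice(lo_, lo_ + _CHUNK)
            buf1s.append(s1[sl]), buf1p.append(p1[sl])
            buf2s.append(s2[sl]), buf2p.append(p2[sl])
            buffered += len(s1[sl])
            if buffered >= _CHUNK:
                flush()

    for code in keys:
        bs, bp = index.bucket_arrays(code)
        nb = len(bs)
        if nb > 1:
            ii, jj = np.triu_indices(nb, k=1)
            push(bs[ii], bp[ii], bs[jj], bp[jj])
        if params.m >= 1:
            for code2 in _cross_partners(code, params.q, params.m, occupied):
                cs, cp = index.bucket_arrays(code2)
                nc = len(cs)
                ii = np.repeat(np.arange(nb), nc)
                jj = np.tile(np.arange(nc), nb)
                push(bs[ii], bp[ii], cs[jj], cp[jj])
    flush()

    nonunique = _mark_sets(ext, len(db))
    return result_from_marks(db, params, params.l, nonunique)
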