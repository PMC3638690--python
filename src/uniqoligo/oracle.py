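"""Brute-force reference solver: all-pairs l-mer comparison.

Ground truth for every correctness test of the filtration engine.  It
shares no code with the engine beyond the base encoding and clean-window
scan, so agreement between the two is evidence rather than tautology: the
oracle never builds a k-mer index, never partitions l-mers into blocks and
never enumerates mutant lists — it simply compares every pair of clean
l-windows directly.

Quadratic in the number of windows; a runtime guard refuses oversized
inputs so misuse fails fast instead of hanging.
"""

from __future__ import annotations

import numpy as np

from .core import EstDatabase
from .search import UniquenessResult, result_from_marks
from .encoding import clean_windows, encode_sequence

__all__ = ["brute_force"]

_ROW_CHUNK = 256


def brute_force(
    db: EstDatabase,
    l: int,
    d: int,
    within_est: bool = False,
    max_windows: int = 20_000,
) -> UniquenessResult:
    """Mark every l-window with a Hamming-<=d partner under the policy.

    Cross-sequence pairs always count; same-sequence pairs at distinct
    starts count only when ``within_est``.  Unique oligos are the clean
    windows left unmarked.
    """
    if l < 1:
        raise ValueError(f"l must be >= 1, got {l}")
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")

    rows: list[np.ndarray] = []
    seq_of: list[int] = []
    start_of: list[int] = []
    for i, (_, seq) in enumerate(db):
        codes = encode_sequence(seq)
        clean = clean_windows(codes, l)
        for p in np.flatnonzero(clean):
            rows.append(codes[p : p + l])
            seq_of.append(i)
            start_of.append(int(p))
    n = len(rows)
    if n > max_windows:
        raise ValueError(
            f"{n} windows exceeds the brute-force guard ({max_windows}); "
            "use the filtration engine for inputs of this size"
        )

    nonunique: list[set[int]] = [set() for _ in range(len(db))]
    if n:
        mat = np.stack(rows)
        seqs = np.array(seq_of, dtype=np.int32)
        marked = np.zeros(n, dtype=bool)
        for lo in range(0, n, _ROW_CHUNK):
            hi = min(lo + _ROW_CHUNK, n)
            hd = np.count_nonzero(
                mat[lo:hi, None, :] != mat[None, :, :], axis=2
            )
            eligible = hd <= d
            if within_est:
                # exclude each window paired with itself
                eligible[np.arange(hi - lo), np.arange(lo, hi)] = False
            else:
                eligible &= seqs[lo:hi, None] != seqs[None, :]
            marked[lo:hi] |= eligible.any(axis=1)
        for w in np.flatnonzero(marked):
            nonunique[seq_of[w]].add(start_of[w])

    return result_from_marks(db, None, l, nonunique)
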