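"""Phase one: file every q-mer occurrence of the database into a k-mer table.

The table maps each q-mer's integer code to the ordered list of its
occurrences ``(seq_index, start)``.  Under uniform base composition each of
the ``4**q`` possible keys carries an expected load of roughly ``n / 4**q``
occurrences, where n is the total symbol count.  Storage is a sparse dict
keyed on occupied codes only; dense key order is recovered by sorting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EstDatabase, OligoOccurrence
from .encoding import encode_sequence, window_codes

__all__ = ["KmerIndex", "BucketStats", "build_index", "bucket_load_stats"]


@dataclass
class KmerIndex:
    """Sparse map from q-mer code to its sorted occurrence list."""

    q: int
    buckets: dict[int, list[OligoOccurrence]] = field(default_factory=dict)
    total_occurrences: int = 0

    def occupied_keys(self) -> np.ndarray:
        """Sorted array of codes with at least one occurrence."""
        return np.array(sorted(self.buckets), dtype=np.int64)

    def bucket_arrays(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        """(seq_indices, starts) of one bucket as int32 arrays."""
        occs = self.buckets[code]
        arr = np.asarray(occs, dtype=np.int32)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class BucketStats:
    """Occupancy summary over the full 4**q key space."""

    table_size: int
    occupied: int
    min_load: int
    max_load: int
    mean_load: float  # total_occurrences / 4**q


def build_index(db: EstDatabase, q: int) -> KmerIndex:
    """Record every clean length-q window of the database into the table.

    Windows containing a non-ACGT base are skipped.  If q exceeds every
    sequence length the index is empty and a warning is issued.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    buckets: dict[int, list[OligoOccurrence]] = {}
    total = 0
    any_window = False
    for i, (_, seq) in enumerate(db):
        codes = encode_sequence(seq)
        win, clean = window_codes(codes, q)
        if len(win):
            any_window = True
        for p in np.flatnonzero(clean):
            buckets.setdefault(int(win[p]), []).append(
                OligoOccurrence(i, int(p))
            )
            total += 1
    if len(db) and not any_window:
        warnings.warn(
            f"q={q} exceeds every sequence length; index is empty",
            stacklevel=2,
        )
    # file order already sorts each bucket by (seq_index, start)
    return KmerIndex(q=q, buckets=buckets, total_occurrences=total)


def bucket_load_stats(index: KmerIndex) -> BucketStats:
    """Min/max/mean occupancy; the mean is taken over all 4**q keys."""
    table_size = 4**index.q
    if not index.buckets:
        return BucketStats(table_size, 0, 0, 0, 0.0)
    sizes = [len(v) for v in index.buckets.values()]
    min_load = min(sizes) if len(index.buckets) == table_size else 0
    return BucketStats(
        table_size=table_size,
        occupied=len(index.buckets),
        min_load=min_load,
        max_load=max(sizes),
        mean_load=index.total_occurrences / table_size,
    )
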