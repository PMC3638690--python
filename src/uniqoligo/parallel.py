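"""Parallel phase two: partition the index key space across workers.

Bucket iterations of the search loop are independent, so the key space is
split into contiguous ranges and each worker runs candidate generation,
extension and verification over the buckets it owns.  Ownership is a pure
function of the key — within-bucket pairs belong to the bucket's owner,
cross-bucket mutant pairs to the owner of the lower key — so every
candidate pair is generated by exactly one worker without coordination
(each worker reads the whole index).  Workers return only their mark
sets; the merge is a set union, commutative and idempotent, so the result
is identical to the serial engine for any worker count.

Ranges are balanced by an estimate of candidate-pair work (sum of squared
bucket sizes), not by key count, since occupancy can be skewed.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import numpy as np

from .core import EstDatabase, SearchParams
from .index import KmerIndex, build_index
from .search import UniquenessResult, find_nonunique, result_from_marks

__all__ = ["WorkPartition", "partition_keys", "find_nonunique_parallel"]

logger = logging.getLogger(__name__)


@dataclass
class WorkPartition:
    """Disjoint sorted key ranges covering all occupied index keys."""

    chunks: list[np.ndarray]  # each a sorted array of occupied keys
    worker_count: int

    def key_ranges(self) -> list[tuple[int, int]]:
        """Half-open code ranges, one per non-empty chunk."""
        return [(int(c[0]), int(c[-1]) + 1) for c in self.chunks if len(c)]


def partition_keys(index: KmerIndex, workers: int) -> WorkPartition:
    """Split occupied keys into ``workers`` contiguous balanced ranges.

    Balancing minimises the spread of per-chunk sum of squared bucket
    sizes (the within-bucket pair count estimate) under the contiguity
    constraint, via greedy accumulation toward the even share.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    keys = index.occupied_keys()
    if not len(keys):
        return WorkPartition(chunks=[], worker_count=workers)
    weights = np.array(
        [len(index.buckets[int(c)]) ** 2 for c in keys], dtype=np.float64
    )
    total = float(weights.sum())
    chunks: list[np.ndarray] = []
    start = 0
    acc = 0.0
    remaining = workers
    for i, w in enumerate(weights):
        acc += w
        # close the chunk once it reaches the even share of what's left,
        # keeping one key per remaining worker available
        n_left = len(keys) - i - 1
        if remaining > 1 and (
            acc >= total / remaining or n_left < remaining - 1
        ):
            chunks.append(keys[start : i + 1])
            total -= acc
            acc = 0.0
            start = i + 1
            remaining -= 1
    chunks.append(keys[start:])
    return WorkPartition(chunks=chunks, worker_count=workers)


def _worker(
    records: list[tuple[str, str]],
    params: SearchParams,
    within_est: bool,
    key_range: tuple[int, int],
) -> list[list[int]]:
    """Run the engine over one key range; return per-sequence mark lists."""
    db = EstDatabase(records=records)
    res = find_nonunique(db, params, within_est=within_est, key_range=key_range)
    return [sorted(s) for s in res.nonunique]


def find_nonunique_parallel(
    db: EstDatabase,
    params: SearchParams,
    workers: int = 1,
    within_est: bool = False,
) -> UniquenessResult:
    """Parallel search; output is identical to the serial engine.

    Each worker rebuilds the (cheap, linear-time) index and processes its
    key range; a worker failure propagates and no partial result is
    returned.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    if workers == 1:
        return find_nonunique(db, params, within_est=within_est)

    index = build_index(db, params.q)
    part = partition_keys(index, workers)
    ranges = part.key_ranges()
    logger.info(
        "partitioned %d occupied keys into %d ranges for %d workers",
        len(index.buckets), len(ranges), workers,
    )
    if not ranges:
        return find_nonunique(db, params, within_est=within_est)

    nonunique: list[set[int]] = [set() for _ in range(len(db))]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        futures = [
            pool.submit(_worker, db.records, params, within_est, rng)
            for rng in ranges
        ]
        for fut in futures:
            for i, marks in enumerate(fut.result()):
                nonunique[i].update(marks)
    return result_from_marks(db, params, params.l, nonunique)
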