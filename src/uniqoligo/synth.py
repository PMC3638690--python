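"""Deterministic synthetic EST database generator with planted repeats.

Emulates the scale of real EST collections — tens to thousands of records
of roughly 200-800 bases — with i.i.d. uniform {A,C,G,T} content.  Planted
repeats copy a donor l-mer into a recipient window with an exact number of
substitutions, giving known-coordinate ground truth: any plant with
``substitutions <= d`` makes both windows non-unique at threshold d.  The
random background can create additional approximate matches, so the plant
list is a guaranteed *subset* of the true non-unique set, never the whole
of it; exact-set assertions belong to the brute-force oracle.

A single integer seed drives all randomness; identical seeds give
byte-identical databases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import EstDatabase
from .encoding import BASES

__all__ = ["PlantSpec", "generate_db", "plant_repeats"]


@dataclass(frozen=True)
class PlantSpec:
    """One planted approximate repeat.

    ``donor`` is ``(seq_index, start)`` of the source window, ``recipient``
    the window overwritten with the mutated copy.  ``substitutions`` is the
    exact Hamming distance between the two windows after planting;
    ``positions`` (offsets within the window) may be left None to be drawn
    at random.  Substituted bases always differ from the original, so the
    planted distance is exact.
    """

    donor: tuple[int, int]
    recipient: tuple[int, int]
    length: int
    substitutions: int
    positions: "tuple[int, ...] | None" = None

    def __post_init__(self) -> None:
        if not 0 <= self.substitutions <= self.length:
            raise ValueError(
                f"substitutions={self.substitutions} outside [0, {self.length}]"
            )
        if self.positions is not None:
            pos = self.positions
            if len(pos) != self.substitutions:
                raise ValueError("positions count != substitutions")
            if len(set(pos)) != len(pos) or any(
                not 0 <= p < self.length for p in pos
            ):
                raise ValueError("positions must be distinct and in [0, length)")


def generate_db(
    num_seqs: int,
    length_range: tuple[int, int],
    seed: int,
    id_prefix: str = "est",
) -> EstDatabase:
    """i.i.d. uniform random database; identical seed, identical output."""
    lo, hi = length_range
    if num_seqs < 1:
        raise ValueError(f"num_seqs must be >= 1, got {num_seqs}")
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(num_seqs)))
    records = []
    for i in range(num_seqs):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        records.append((f"{id_prefix}_{i:0{width}d}", seq))
    return EstDatabase(records=records)


def _window_span(loc: tuple[int, int], length: int) -> tuple[int, int, int]:
    seq, start = loc
    return seq, start, start + length


def plant_repeats(
    db: EstDatabase,
    plants: list[PlantSpec],
    seed: int = 0,
) -> tuple[EstDatabase, list[PlantSpec]]:
    """Write each plant's mutated donor copy into its recipient window.

    Returns the modified database and the realised plant list (random
    substitution positions filled in).  For any threshold
    ``d >= substitutions``, both the donor and the recipient window of a
    plant are guaranteed non-unique.

    Recipient windows may not overlap each other or any donor window —
    overlap would silently change a planted distance and break the ground
    truth, so it is an error.
    """
    rng = np.random.default_rng(seed)
    seqs = [list(s) for s in db.sequences]

    spans = []
    for spec in plants:
        for role, loc in (("donor", spec.donor), ("recipient", spec.recipient)):
            si, a, b = _window_span(loc, spec.length)
            if not (0 <= si < len(seqs)):
                raise ValueError(f"{role} sequence index {si} out of range")
            if a < 0 or b > len(seqs[si]):
                raise ValueError(f"{role} window [{a},{b}) out of bounds")
            if any(c not in BASES for c in seqs[si][a:b]):
                raise ValueError(f"{role} window [{a},{b}) is not clean DNA")
            spans.append((role, si, a, b))
    recips = [s for s in spans if s[0] == "recipient"]
    others = [s for s in spans if s[0] == "donor"]
    for i, (_, si, a, b) in enumerate(recips):
        for _, sj, c, e in recips[:i] + others:
            if si == sj and a < e and c < b:
                raise ValueError(
                    "overlapping plant windows: ground truth would be ambiguous"
                )

    realised: list[PlantSpec] = []
    for spec in plants:
        ds, dp = spec.donor
        rs, rp = spec.recipient
        window = list(db.sequences[ds][dp : dp + spec.length])
        if spec.positions is None:
            pos = tuple(
                sorted(
                    int(p)
                    for p in rng.choice(
                        spec.length, size=spec.substitutions, replace=False
                    )
                )
            )
        else:
            pos = tuple(sorted(spec.positions))
        for p in pos:
            alternatives = [b for b in BASES if b != window[p]]
            window[p] = alternatives[int(rng.integers(0, 3))]
        seqs[rs][rp : rp + spec.length] = window
        realised.append(replace(spec, positions=pos))

    new_db = EstDatabase(
        records=[(rid, "".join(s)) for (rid, _), s in zip(db.records, seqs)]
    )
    return new_db, realised
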