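"""Domain types and Hamming-distance primitives for unique-oligo screening.

The problem: given a database of ESTs (short DNA fragments, typically
200-800 bp) and integers ``l`` and ``d``, find every l-mer that occurs in
exactly one EST and has no approximate occurrence (Hamming distance <= d)
in any other EST.  Such l-mers are *unique oligos* and serve as
sequence-specific probes or primers.

The solvers in :mod:`uniqoligo.search` rely on a pigeonhole argument: if two
l-mers are within Hamming distance d and both are cut into k blocks, some
block pair must match within a small per-block mismatch budget m.  Three
partition schemes trade block count against budget:

========================  ==============  ===
scheme                    blocks k        m
========================  ==============  ===
``Scheme.EXACT``          d + 1           0
``Scheme.ONE_MISMATCH``   floor(d/2) + 1  1
``Scheme.TWO_MISMATCH``   floor(d/3) + 1  2
========================  ==============  ===

Each scheme is complete: a per-block mismatch load above m in every block
would force a total distance above d.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "Scheme",
    "SearchParams",
    "EstDatabase",
    "OligoOccurrence",
    "hamming",
    "derive_params",
    "block_starts",
]

_VALID_BASES = frozenset("ACGT")


class Scheme(enum.Enum):
    """Pigeonhole partition scheme for the seed filter."""

    EXACT = "exact"
    ONE_MISMATCH = "one-mismatch"
    TWO_MISMATCH = "two-mismatch"

    @classmethod
    def from_name(cls, name: "str | Scheme") -> "Scheme":
        if isinstance(name, Scheme):
            return name
        key = name.strip().lower().replace("_", "-")
        for member in cls:
            if member.value == key:
                return member
        raise ValueError(
            f"unknown scheme {name!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


# per-scheme (block-count function of d, per-block mismatch budget m)
_SCHEME_RULES = {
    Scheme.EXACT: (lambda d: d + 1, 0),
    Scheme.ONE_MISMATCH: (lambda d: d // 2 + 1, 1),
    Scheme.TWO_MISMATCH: (lambda d: d // 3 + 1, 2),
}


class OligoOccurrence(NamedTuple):
    """Location of one k-mer: ``(seq_index, start)``, 0-based."""

    seq_index: int
    start: int


@dataclass(frozen=True)
class SearchParams:
    """Derived search parameters.

    Attributes
    ----------
    l : oligo length in bases.
    d : maximum Hamming distance for an approximate occurrence.
    scheme : partition scheme (see :class:`Scheme`).
    q : seed length; each l-mer block is indexed by its length-q prefix.
    k : number of blocks the l-mer is cut into.
    m : per-block mismatch budget (0, 1 or 2).
    """

    l: int
    d: int
    scheme: Scheme
    q: int
    k: int
    m: int

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError(f"l must be >= 1, got {self.l}")
        if self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")
        if not (1 <= self.q <= self.l):
            raise ValueError(f"q={self.q} out of range [1, l={self.l}]")
        if self.k * self.q > self.l:
            raise ValueError(
                f"k*q = {self.k * self.q} exceeds l = {self.l}; "
                "every block must have length >= q"
            )


def derive_params(
    l: int,
    d: int,
    scheme: "str | Scheme",
    q_override: "int | None" = None,
) -> SearchParams:
    """Derive (q, k, m) for oligo length ``l``, distance ``d`` and a scheme.

    ``q`` defaults to ``floor(l/k)`` so that every block — including the
    last, which absorbs the remainder — has length at least q.  A block
    matching within m mismatches then guarantees its length-q prefix also
    matches within m, so indexing only length-q seeds loses no candidates.

    ``q_override`` substitutes a custom seed length; it must still satisfy
    ``k * q <= l``.

    >>> derive_params(28, 6, Scheme.ONE_MISMATCH).q
    7
    """
    if l < 1:
        raise ValueError(f"l must be >= 1, got {l}")
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    scheme = Scheme.from_name(scheme)
    k_of_d, m = _SCHEME_RULES[scheme]
    k = k_of_d(d)
    if l < k:
        raise ValueError(
            f"l={l} is smaller than the block count k={k} for scheme "
            f"{scheme.value} at d={d}: blocks would be empty"
        )
    q = l // k if q_override is None else q_override
    return SearchParams(l=l, d=d, scheme=scheme, q=q, k=k, m=m)


def block_starts(params: SearchParams) -> list[int]:
    """Offsets of the length-q seed of each block within an l-mer.

    Blocks tile ``[0, l)`` as ``[0,q), [q,2q), ..., [(k-1)q, l)``; the final
    block spans to ``l`` and has length >= q.  The seed of block j starts at
    ``j*q``.
    """
    return [j * params.q for j in range(params.k)]


def hamming(x: str, y: str) -> int:
    """Hamming distance between two equal-length strings.

    Raises
    ------
    ValueError
        If the strings differ in length (distance undefined).
    """
    if len(x) != len(y):
        raise ValueError(
            f"hamming distance undefined for lengths {len(x)} != {len(y)}"
        )
    return sum(a != b for a, b in zip(x, y))


@dataclass
class EstDatabase:
    """Ordered collection of named DNA sequences (the EST database).

    Sequences are uppercased on construction.  Characters outside
    {A,C,G,T} (e.g. N) are retained in the stored string but any k-mer
    window containing one is excluded from indexing and search downstream.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned: list[tuple[str, str]] = []
        seen: set[str] = set()
        for rec_id, seq in self.records:
            if rec_id in seen:
                raise ValueError(f"duplicate record id {rec_id!r}")
            seen.add(rec_id)
            cleaned.append((rec_id, seq.upper()))
        self.records = cleaned

    @property
    def n(self) -> int:
        """Total symbol count across all sequences."""
        return sum(len(seq) for _, seq in self.records)

    @property
    def ids(self) -> list[str]:
        return [rec_id for rec_id, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def with_reverse_complements(self) -> "EstDatabase":
        """Append each sequence's reverse complement as a shadow record.

        Shadow records are named ``<id>__rc``; callers mapping hits back to
        forward coordinates can recognise them by that suffix.  Off by
        default throughout the package: uniqueness is defined on the given
        strand unless explicitly requested otherwise.
        """
        comp = str.maketrans("ACGTN", "TGCAN")
        extra = [
            (rec_id + "__rc", seq.translate(comp)[::-1])
            for rec_id, seq in self.records
        ]
        return EstDatabase(records=self.records + extra)
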