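"""2-bit integer encoding of k-mers and Hamming-ball (mutant) enumeration.

A q-mer over {A,C,G,T} is encoded as a base-4 integer in ``[0, 4**q)`` with
digit map A=0, C=1, G=2, T=3, most significant digit first.  The code is
the hash-table key used by :mod:`uniqoligo.index`; the digit assignment is
a convention and no result depends on it.

The *m-mutant list* of a q-mer is every q-mer at Hamming distance 1..m from
it — the string itself is excluded, so the list has exactly ``3q`` entries
for m=1 and ``9q(q-1)/2 + 3q`` for m=2.  Mutants are generated directly in
code space (digit substitutions) in a deterministic order: increasing
mutated position, then increasing substituted digit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BASES",
    "encode",
    "decode",
    "encode_sequence",
    "window_codes",
    "mutant_codes",
    "mutant_list_size",
]

BASES = "ACGT"

_CODE_OF = {b: i for i, b in enumerate(BASES)}

# 256-entry lookup: ASCII byte -> 2-bit code, -1 for anything not ACGT
_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in _CODE_OF.items():
    _LUT[ord(_b)] = _c


def encode(s: str) -> int:
    """Encode a q-mer string as its base-4 integer code.

    Raises
    ------
    ValueError
        On a character outside {A,C,G,T}, naming the offending position.
    """
    code = 0
    for pos, ch in enumerate(s):
        try:
            digit = _CODE_OF[ch]
        except KeyError:
            raise ValueError(
                f"invalid base {ch!r} at position {pos}: not one of {BASES}"
            ) from None
        code = (code << 2) | digit
    return code


def decode(code: int, q: int) -> str:
    """Inverse of :func:`encode`: the q-mer string for an integer code."""
    if not 0 <= code < 4**q:
        raise ValueError(f"code {code} out of range [0, 4^{q})")
    out = []
    for shift in range(2 * (q - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def encode_sequence(seq: str) -> np.ndarray:
    """Per-base 2-bit codes for a DNA string; -1 marks non-ACGT characters.

    Returns an int8 array of ``len(seq)`` entries.  Windows containing a
    -1 are "dirty" and are skipped by indexing and search.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def window_codes(codes: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of every length-q window of an encoded sequence.

    Parameters
    ----------
    codes : int8 array from :func:`encode_sequence`.
    q : window length.

    Returns
    -------
    (win_codes, clean) : int64 array and bool array, both of length
        ``max(0, len(codes) - q + 1)``.  ``win_codes[p]`` is valid only
        where ``clean[p]`` — windows touching a non-ACGT base carry an
        arbitrary code and ``clean[p]`` is False.
    """
    n = len(codes)
    nwin = n - q + 1
    if nwin <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bad = (codes < 0).astype(np.int64)
    badcum = np.concatenate([[0], np.cumsum(bad)])
    clean = (badcum[q:] - badcum[:-q]) == 0
    safe = np.where(codes < 0, 0, codes).astype(np.int64)
    win = np.zeros(nwin, dtype=np.int64)
    for i in range(q):
        win = (win << 2) | safe[i : i + nwin]
    return win, clean


def clean_windows(codes: np.ndarray, length: int) -> np.ndarray:
    """Boolean mask of windows of ``length`` free of non-ACGT bases."""
    n = len(codes)
    nwin = n - length + 1
    if nwin <= 0:
        return np.empty(0, dtype=bool)
    bad = (codes < 0).astype(np.int64)
    badcum = np.concatenate([[0], np.cumsum(bad)])
    return (badcum[length:] - badcum[:-length]) == 0


def mutant_list_size(q: int, m: int) -> int:
    """Closed-form mutant-list cardinality: 3q for m=1, 9q(q-1)/2+3q for m=2."""
    if m == 1:
        return 3 * q
    if m == 2:
        return 9 * q * (q - 1) // 2 + 3 * q
    raise ValueError(f"unsupported m={m}; expected 1 or 2")


def mutant_codes(code: int, q: int, m: int) -> list[int]:
    """All codes at Hamming distance in [1, m] from ``code`` (itself excluded).

    Generated by digit substitution in code space; order is deterministic
    (increasing mutated position from the left, then increasing digit), so
    runs are reproducible.
    """
    if not 0 <= code < 4**q:
        raise ValueError(f"code {code} out of range [0, 4^{q})")
    if m not in (1, 2):
        raise ValueError(f"unsupported m={m}; expected 1 or 2")

    shifts = [2 * (q - 1 - i) for i in range(q)]  # position 0 = leftmost base
    digits = [(code >> s) & 3 for s in shifts]

    out: list[int] = []
    for i in range(q):
        base_i = code - (digits[i] << shifts[i])
        for v in range(4):
            if v == digits[i]:
                continue
            out.append(base_i + (v << shifts[i]))
    if m == 2:
        for i in range(q):
            base_i = code - (digits[i] << shifts[i])
            for j in range(i + 1, q):
                base_ij = base_i - (digits[j] << shifts[j])
                for v in range(4):
                    if v == digits[i]:
                        continue
                    partial = base_ij + (v << shifts[i])
                    for w in range(4):
                        if w == digits[j]:
                            continue
                        out.append(partial + (w << shifts[j]))
    return out
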