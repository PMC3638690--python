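"""Parameter derivation, block geometry and the Hamming primitive."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uniqoligo import (
    EstDatabase,
    Scheme,
    block_starts,
    derive_params,
    hamming,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ("ACGT", "ACGT", 0),
        ("AAAA", "TTTT", 4),
        ("ACGTACG", "ACCTACG", 1),
        ("", "", 0),
    ],
)
def test_hamming_examples(x, y, expected):
    assert hamming(x, y) == expected


def test_hamming_rejects_length_mismatch():
    with pytest.raises(ValueError):
        hamming("ACG", "AC")


@settings(derandomize=True, max_examples=100)
@given(dna, dna, dna)
def test_hamming_metric_axioms(a, b, c):
    n = min(len(a), len(b), len(c))
    a, b, c = a[:n], b[:n], c[:n]
    assert hamming(a, b) == hamming(b, a)
    assert hamming(a, a) == 0
    assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


@pytest.mark.parametrize(
    "l,d,scheme,q,k,m",
    [
        (28, 6, Scheme.ONE_MISMATCH, 7, 4, 1),
        (28, 6, Scheme.EXACT, 4, 7, 0),
        (27, 6, Scheme.TWO_MISMATCH, 9, 3, 2),
    ],
)
def test_derive_params_reference_configurations(l, d, scheme, q, k, m):
    """The three published (l, d, scheme) -> q derivations."""
    p = derive_params(l, d, scheme)
    assert (p.q, p.k, p.m) == (q, k, m)


@pytest.mark.parametrize("scheme", list(Scheme))
@pytest.mark.parametrize("l", [5, 12, 27, 28, 40])
@pytest.mark.parametrize("d", [0, 1, 2, 3, 6])
def test_derive_params_invariants(l, d, scheme):
    try:
        p = derive_params(l, d, scheme)
    except ValueError:
        k_of_d = {
            Scheme.EXACT: d + 1,
            Scheme.ONE_MISMATCH: d // 2 + 1,
            Scheme.TWO_MISMATCH: d // 3 + 1,
        }[scheme]
        assert l < k_of_d  # only empty blocks may be rejected
        return
    assert 1 <= p.q <= p.l
    assert p.k * p.q <= p.l
    expected_k = {
        Scheme.EXACT: d + 1,
        Scheme.ONE_MISMATCH: d // 2 + 1,
        Scheme.TWO_MISMATCH: d // 3 + 1,
    }[scheme]
    assert p.k == expected_k
    assert p.q == l // p.k


def test_derive_params_rejects_empty_blocks():
    # EXACT at d=6 needs 7 blocks; l=5 cannot host them
    with pytest.raises(ValueError):
        derive_params(5, 6, Scheme.EXACT)


def test_derive_params_scheme_names_and_bad_override():
    assert derive_params(28, 6, "one_mismatch").q == 7
    with pytest.raises(ValueError):
        derive_params(28, 6, "exact", q_override=5)  # 7*5 > 28
    with pytest.raises(ValueError):
        Scheme.from_name("three-mismatch")


@pytest.mark.parametrize(
    "l,d,scheme,expected",
    [
        (28, 6, Scheme.ONE_MISMATCH, [0, 7, 14, 21]),
        (27, 6, Scheme.TWO_MISMATCH, [0, 9, 18]),
        (5, 0, Scheme.EXACT, [0]),
    ],
)
def test_block_starts(l, d, scheme, expected):
    assert block_starts(derive_params(l, d, scheme)) == expected


@pytest.mark.parametrize("scheme", list(Scheme))
@pytest.mark.parametrize("l,d", [(11, 2), (28, 6), (13, 5), (9, 6)])
def test_blocks_tile_the_lmer(l, d, scheme):
    """Blocks [jq,(j+1)q) for j<k-1 plus [(k-1)q, l) cover [0,l) disjointly."""
    try:
        p = derive_params(l, d, scheme)
    except ValueError:
        pytest.skip("blocks would be empty for this (l, d, scheme)")
    starts = block_starts(p)
    covered = []
    for j, s in enumerate(starts):
        end = starts[j + 1] if j + 1 < len(starts) else p.l
        assert end - s >= p.q  # every block hosts a full-length seed
        covered.extend(range(s, end))
    assert covered == list(range(p.l))


def test_est_database_validation():
    db = EstDatabase(records=[("a", "acgt"), ("b", "NNAA")])
    assert db.sequences == ["ACGT", "NNAA"]
    assert db.n == 8
    with pytest.raises(ValueError):
        EstDatabase(records=[("a", "ACGT"), ("a", "TTTT")])


def test_reverse_complement_shadow_records():
    db = EstDatabase(records=[("a", "AACG")]).with_reverse_complements()
    assert db.records == [("a", "AACG"), ("a__rc", "CGTT")]
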