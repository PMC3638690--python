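# Methods

## Model and definitions

The input is an EST database `D = {x₁, …, x_k}` of DNA strings over
{A,C,G,T} with `n` total symbols. An `l`-mer `y` *occurs approximately* in
`D` if some substring `z` of some EST satisfies `HD(y, z) ≤ d`, where `HD`
is the Hamming distance. A *unique oligo* is an `l`-mer that occurs in one
EST and occurs approximately in no other EST. The package finds all unique
oligos, reporting both the non-unique window positions and the surviving
unique oligos per sequence.

## The filtration algorithms

All three solvers are two-phase. Phase one files every length-`q` window
of the database into a table keyed on the window's base-4 integer code
(A=0, C=1, G=2, T=3, most significant digit first; the assignment is a
convention and no result depends on it). Each bucket holds the occurrence
list `{(sequence index, position)}` of one `q`-mer; under uniform
composition the expected bucket load is `n / 4^q`.

Phase two generates candidate seed pairs — all unordered pairs within each
bucket, plus, for schemes with budget `m ≥ 1`, all pairs between a bucket
and each occupied bucket in its `m`-mutant list (each unordered bucket
pair visited once, owned by the lower key). Each seed pair is extended to
the aligned `l`-mer pairs that contain the seeds at the same block offset:
for block index `j` the candidate `l`-mer starts are `(p₁ − jq, p₂ − jq)`.
Candidates in bounds with clean windows are verified by an exact Hamming
test against `d`; both members of every verified cross-sequence pair are
marked non-unique.

Completeness rests on the pigeonhole bound. Cut both `l`-mers into `k`
blocks; if every block pair had more than `m` mismatches, the total would
be at least `k(m+1)`, which exceeds `d` for each scheme (`(d+1)·1`,
`(⌊d/2⌋+1)·2`, `(⌊d/3⌋+1)·3` are all ≥ `d+1`). Hence some block pair
matches within `m`, and because every block has length ≥ `q` and contains
its length-`q` seed prefix as a subset, the seed prefixes of that block
also match within `m` — so the pair is found by the seed filter.
Soundness is immediate: nothing is marked without passing the exact
verification, which also keeps degenerate parameter choices correct (at
`d ∈ {0,1}` the one-mismatch scheme has `k = 1`, `q = l`, `m = 1` and the
seed filter over-matches; verification restores the `HD ≤ d` semantics).

### Block geometry: q = ⌊l/k⌋

Seeds use `q = ⌊l/k⌋`, blocks tile `[0, l)` as
`[0,q), [q,2q), …, [(k−1)q, l)`, and the final block absorbs the
remainder, so every block has length ≥ `q`. The alternative (ceiling
block lengths with a short final block) would let matches confined to a
short last block escape a length-`q` seed index. With the floor
convention `k·q ≤ l` always holds, and for the reference configurations
(`l` divisible by `k`) floor and ceiling coincide: `(28,6)` gives `q = 7`
under the one-mismatch scheme and `q = 4` under the exact scheme, and
`(27,6)` gives `q = 9` under the two-mismatch scheme.

### Extension is block-aligned, not scanning

Candidates are generated only at the `k` block-aligned offsets, not at all
`l − q + 1` relative shifts. The pigeonhole argument guarantees the
matching seed occupies the *same* block index in both `l`-mers, so
block-aligned extension is complete; this is the main constant-factor
saving over a scanning extension and is validated by the oracle-equivalence
suite.

## Policies and conventions

- **Uniqueness policy.** "Occurs in exactly one EST" is read as: an oligo
  is unique iff no `HD ≤ d` occurrence exists in a *different* EST.
  Same-EST repeats do not disqualify by default; `within_est=True`
  (CLI `--within-est`) enables the stricter policy, under which
  same-sequence pairs at distinct starts also mark.
- **Counting.** Reported non-unique totals count marked window positions
  summed over sequences; two identical `l`-mer strings at different
  positions are counted (and marked) independently.
- **Ambiguous bases.** Sequences are uppercased on load; any window
  containing a character outside {A,C,G,T} is excluded from indexing and
  search and is reported neither unique nor non-unique.
- **Coordinates** are 0-based, half-open everywhere, including the TSV and
  BED outputs.
- **Strand.** Matching is forward-strand only by default; `--revcomp`
  appends each sequence's reverse complement as a shadow record.
- **Determinism.** Marking is idempotent and the mark sets are unions, so
  the output is independent of candidate enumeration order; mutant lists
  are generated in a fixed order (increasing mutated position, then digit)
  so any streamed inspection is reproducible too.

## Parameters

| parameter | meaning | default |
|-----------|---------|---------|
| `l` | oligo length, bases | user-set; 27–28 typical for probes |
| `d` | max mismatches for approximate occurrence | user-set; 6 typical at l≈28 |
| `scheme` | seed partition scheme | `one-mismatch` (CLI) |
| `q` | seed length | `⌊l/k⌋`, overridable (`k·q ≤ l` enforced) |
| `workers` | parallel workers | 1 |

## Parallel execution

Bucket iterations are independent, so the occupied key space is split into
contiguous ranges balanced by the sum of squared bucket sizes (the
within-bucket pair-count estimate), which tolerates skewed occupancy.
Ownership is a pure function of the key — within-bucket pairs belong to
the bucket's owner, cross-bucket mutant pairs to the lower key's owner —
so every pair is generated exactly once without coordination; each worker
reads the whole index (rebuilt per worker, linear time) and returns only
its mark sets. The merge is a set union (commutative, idempotent), making
the parallel result bit-identical to the serial one for any worker count;
the test suite asserts this for 1–4 workers. Speedup is hardware-dependent
and is logged, never asserted.

## The brute-force oracle

`brute_force` compares every pair of clean `l`-windows directly
(vectorised, chunked) and shares no code with the engine beyond the base
encoding and the clean-window scan — no index, no blocks, no mutant lists —
so engine/oracle agreement is evidence rather than tautology. A guard
refuses inputs above 20 000 windows (quadratic cost) so misuse fails fast.

## Synthetic data

The generator emulates the scale of real EST collections: i.i.d. uniform
{A,C,G,T} records with lengths drawn from a user range (defaults 200–800
bases, 78 records in the CLI, mirroring a small real-world collection).
A single integer seed drives all randomness; identical seeds give
byte-identical FASTA. Planted repeats copy a donor `l`-mer into a
recipient window with an exact substitution count (substituted bases
always change), giving known-coordinate ground truth: every plant with
`substitutions ≤ d` is guaranteed non-unique. The random background may
itself contain approximate matches, so the plant list is a *subset* of the
true non-unique set; exact-set assertions always go through the oracle.

What the generator does not emulate: real EST composition bias, poly-A
tails, sequencing error profiles, or shared gene families. Passing tests
therefore demonstrate algorithmic correctness (set equality with
exhaustive comparison) on realistic scales, not biological
characterisation of any particular organism's EST collection.

## Test-scale choices

The oracle-equivalence panel uses 200 seeded databases spanning 5–30
sequences of 50–400 bases with `l ∈ [8, 28]` and `d ∈ [0, 6]`; most cases
sit at the small end of those ranges, with every twentieth case drawn
full-size, which keeps the panel's total runtime modest while still
exercising the large regime. The exhaustive pigeonhole check runs over
mismatch *position sets* (all `C(l, ≤d)` subsets for `l ≤ 12`, `d ≤ 6`)
rather than over `4^l` sequence pairs — block mismatch counts depend only
on which positions differ, so this is exact, not sampled.

## Known limitations

- Hamming distance only: insertions/deletions are out of scope.
- The dense-table memory model of the original formulation is replaced by
  a sparse dict keyed on occupied codes, so user-overridden large `q`
  stays memory-proportional to distinct `q`-mers.
- `q` overrides that violate `k·q ≤ l` are rejected rather than silently
  truncated.
- The oracle is quadratic by design and guarded; it is a reference, not a
  production path.
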