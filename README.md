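# uniqoligo

Unique oligonucleotide search in EST databases via pigeonhole k-mer
filtration.

## The problem

An EST (Expressed Sequence Tag) database is a collection of short DNA
fragments, typically 200–800 bases each. A length-`l` oligo (`l`-mer) that
occurs in exactly one EST — and has no near-identical copy anywhere else —
can serve as a sequence-specific probe or PCR primer for that EST. Two
oligos are considered near-identical when their Hamming distance (number of
mismatching positions) is at most a threshold `d`. The *unique oligos
search problem* asks for every `l`-mer `u` that occurs in one EST and has
no occurrence `z` with `HD(u, z) ≤ d` in any other EST. Typical settings
are `l = 27` or `28` and `d = 6`.

Comparing all pairs of `l`-windows is quadratic and slow. `uniqoligo`
implements three filtration algorithms built on a pigeonhole argument: if
`HD(l₁, l₂) ≤ d` and both `l`-mers are cut into `k` blocks, then some block
pair must match within a per-block budget `m` — otherwise the total
distance would exceed `d`. Each scheme indexes the length-`q` seed prefix
of every block (`q = ⌊l/k⌋`) in a hash table keyed on the seed's 2-bit
integer code, then only extends and verifies seed pairs that match within
`m` mismatches:

| scheme         | blocks `k`   | seed budget `m` | seed pairing             |
|----------------|--------------|-----------------|--------------------------|
| `exact`        | `d + 1`      | 0               | identical seeds only     |
| `one-mismatch` | `⌊d/2⌋ + 1`  | 1               | seed vs its 1-mutants    |
| `two-mismatch` | `⌊d/3⌋ + 1`  | 2               | seed vs its 2-mutants    |

The *m-mutant list* of a `q`-mer is every `q`-mer within Hamming distance
`m` of it (itself excluded): `3q` strings for `m = 1` and `9q(q−1)/2 + 3q`
for `m = 2`. Every candidate pair surviving the filter is verified by an
exact Hamming-distance test, so all three schemes return exactly the same
answer as the brute-force all-pairs comparison — the filter only decides
how much work verification has to do. A brute-force oracle
(`uniqoligo.brute_force`) is included and is used throughout the test suite
as ground truth, and a parallel driver partitions the hash-table key space
across workers with results identical to the serial engine.

## Worked example

Generate a synthetic EST database with one planted approximate repeat (a
28-mer copied from `est_000` position 10 into `est_005` position 40 with
exactly 4 substitutions), then search it:

```sh
uniqoligo synth --num 8 --seed 7 --min-len 100 --max-len 200 \
    --plant 0:10:5:40:28:4 --out ests.fasta
uniqoligo search ests.fasta --l 28 --d 6 --scheme one-mismatch --out run
```

The search logs:

```
INFO uniqoligo: loaded 8 records, 1341 symbols
INFO uniqoligo: scheme=one-mismatch derived q=7 k=4 m=1
INFO uniqoligo: index: 1244/16384 buckets occupied, mean load 0.0789, max 2
INFO uniqoligo: non-unique oligos: 12; unique oligos: 1113
```

Reading the numbers: with `l = 28`, `d = 6` the one-mismatch scheme cuts
each 28-mer into `k = 4` blocks and indexes `q = 7`-mer seeds into a table
of `4⁷ = 16384` keys (mean bucket load `n/4⁷ ≈ 0.08`). The planted copy
(Hamming distance 4 ≤ 6) makes the donor window, the recipient window and
a few overlapping windows non-unique — 12 marked window positions in all,
6 in each of the two sequences involved — while the remaining 1113 clean
windows are unique oligos. `run.unique.tsv` lists each unique oligo as
`seq_id  start  end  oligo` (0-based half-open), and `run.summary.tsv`
gives per-sequence window counts. `uniqoligo check ests.fasta --l 12 --d 2`
re-runs all three schemes against the brute-force oracle and exits non-zero
on any disagreement.

The same functionality is available as a library:

```python
from uniqoligo import derive_params, find_nonunique, generate_db

db = generate_db(8, (100, 200), seed=7)
params = derive_params(28, 6, "one-mismatch")   # q=7, k=4, m=1
result = find_nonunique(db, params)
print(result.n_nonunique, result.n_unique)
```

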