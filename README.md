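# wildtrie

Deduplication of high-throughput sequencing reads that treats the ambiguous
base `N` as a wildcard, built on a prefix tree (trie) with wildcard-aware
search.

## The problem

PCR amplification during library preparation produces duplicate reads that
must be collapsed before counting anything — templates in a B-cell-receptor
repertoire, UMIs, coverage. Sequencers also emit low-quality base calls,
conventionally masked to `N`. Two reads from the same template can then
*look* different while differing only at masked positions, so hash-based
exact matching (the fast default in most tools) over-counts unique
sequences, while scanning every read against every accepted read handles
`N`s correctly but costs O(m·n²) and becomes infeasible beyond a few
thousand reads.

Define two same-length reads as **equivalent** when every position agrees
literally or is `N` on either side. The relation is reflexive and symmetric
but *not* transitive (`TAC ~ TNC ~ TGC`, yet `TAC ≁ TGC`), so a deduplicated
set is a **maximal independent set (MIS)** of the equivalence graph: the
retained representatives are pairwise non-equivalent and every removed read
is equivalent to its representative. An MIS is not unique — the toy graph
above admits both `{TAC, TGC}` and `{TNC}` — so reads are processed in
ascending order of `N` count, which keeps the least-ambiguous reads as
representatives.

`wildtrie` stores admitted sequences in a trie with one child slot per
alphabet symbol (`A,C,G,T` then `N` last; one shared symbol→slot table for
all nodes). Searching a query walks one node per position; a stored or query
`N` forks the walk, and a mismatch prunes the whole subtree, so a
wildcard-free lookup costs O(m) and a query with at most k `N`s costs
O(m·5ᵏ) in the worst case — in practice near-linear total work where the
pairwise scan is quadratic. A progressive pairwise baseline and an
exact-matching baseline are included for verification and comparison, along
with a simulator that generates reads with known ground truth.

## Worked example

```python
from wildtrie import SeqRecord, dedup_trie

reads = [SeqRecord(f"r{i}", s) for i, s in enumerate(["TAC", "TNC", "TGC"])]
result = dedup_trie(reads)
print([r.seq for r in result.representatives])  # ['TAC', 'TGC']
print(result.assignment)   # {'r0': 'r0', 'r1': 'r0', 'r2': 'r2'}
print(result.multiplicity) # {'r0': 2, 'r2': 1}
```

`TNC` is equivalent to both neighbours; after the ascending-`N` sort the
unambiguous tips are admitted first and `TNC` collapses onto the
earliest-admitted match (`TAC`), carrying its count into `multiplicity`.

The `examples/` scripts each exercise one capability and print what the
numbers mean; `examples/03_simulate_recovery.py` for instance simulates
2000 reads of 200 bp with 1% `N`s and prints

```
distinct parents sampled (truth): 1272
wildcard trie dedup size        : 1272
exact-matching dedup size       : 2000
```

— the trie recovers the true template count exactly while exact matching
inflates it 1.57-fold, because every distinct `N` pattern looks new.

## Command line

```bash
wildtrie mask   -i raw.fastq -o masked.fastq --mask-quality 10   # Q<=10 -> N
wildtrie dedup  -i masked.fastq -o unique.fastq --map-out map.tsv
wildtrie simulate --n-parents 10000 --n-reads 10000 --length 200 \
                  --mask-fraction 0.01 --seed 1 -o sim.fasta --truth-out truth.tsv
wildtrie bench  --n 100 --n 1000 --mask-fraction 0.05 -o bench.csv
```

FASTA/FASTQ, plain or gzipped, are auto-detected. Logs go to stderr, data
to files/stdout.

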