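# Methods

## Model

A read is a string over a fixed alphabet with one designated wildcard
symbol, `N` for DNA. Two reads are *equivalent* iff they have equal length
and agree at every position up to the wildcard. The relation is reflexive
and symmetric but not transitive, so "collapse equivalent reads" is not a
partition: the deduplicated set is a maximal independent set (MIS) of the
equivalence graph — representatives pairwise non-equivalent, every input
equivalent to its representative. MIS are not unique, and greedy MIS
construction is order-dependent. All methods here fix the same order:
ascending wildcard count, ties in input order (a stable sort). This prefers
unambiguous reads as representatives and makes every run reproducible.
`presorted=True` bypasses the sort for callers who want a different greedy
order (e.g. the center-of-the-star MIS).

Three methods share the preprocessing (exact string collapsing first, then
the sort):

* **trie** — admitted sequences live in a prefix tree; membership is a
  wildcard-aware DFS.
* **pairwise** — membership scans the admitted list with the equivalence
  predicate, stopping at the first match. It is the reference oracle: the
  two methods must produce identical results, and the tests assert that on
  randomized instances.
* **exact** — literal string identity only (`N` a fifth letter); the fast
  hash-based behaviour most tools implement, kept as the inflation baseline.

## Trie layout and traversal

Every node is a fixed-size child list — one slot per alphabet symbol, the
wildcard slot last — plus a terminal flag; `__slots__` suppresses the
per-instance dict, and a single shared symbol→index table serves all nodes.
This restricted-dictionary layout is what keeps a node at two machine words
of Python payload and the million-node tries affordable.

Search at depth *p*: a regular query symbol tries its own slot then the
wildcard slot (a stored `N` matches anything); a wildcard query symbol
tries every occupied slot, regular symbols first, wildcard last. The branch
order is fixed so both the boolean result and the visit counters are
deterministic. A match requires a terminal flag exactly at the query's
length, so mixed-length inputs are safe and a stored prefix never matches.
The traversal uses an explicit stack rather than recursion, so query length
is bounded by memory, not the interpreter recursion limit (tested at
length 2000). The boolean search short-circuits on the first matching
branch.

Cost accounting is hardware-free: `node_visits` counts nodes popped from
the traversal stack (root included), `comparisons` counts equivalence-
predicate calls in the pairwise method. A wildcard-free lookup costs at
most m+1 visits for an m-base query; with at most k wildcards per read the
worst case is O(m·5ᵏ) per query, and the node count is bounded by
1 + Σ len(s) over stored sequences.

## Assignment bookkeeping

When a duplicate matches more than one admitted sequence (possible because
the relation is not transitive), the two methods' natural "first match"
differs: the pairwise scan meets stored sequences in admission order, a
trie DFS meets them in slot order. To make results method-independent, both
assign a duplicate to the **earliest-admitted** equivalent representative.
The pairwise scan gets this for free and keeps its short-circuit; the trie
assignment path enumerates all matching terminals (`find_matches`) and
picks the one with the lowest admission index. The membership-only search
(`search`) remains short-circuiting. Enumeration only adds work on
successful queries, where the DFS has already paid for the matching
branches; the scaling behaviour is unchanged.

Exact-duplicate groups are collapsed before any equivalence test and travel
as a unit: the group inherits the key read (first seen, lowest input rank),
its wildcard count, and its sort position, and multiplicities fold the
group size into the representative's count. Multiplicity reporting is an
extension beyond plain duplicate removal; it never changes the
representative set and is emitted only as an optional TSV sidecar.

## Quality masking

Phred scores encode the estimated base-call error probability as
Q = −10·log₁₀(P); masking replaces bases with Q ≤ threshold by the
wildcard. The comparison is inclusive, threshold 10 by default
(conventional; 20 is the common stricter choice), Phred+33 encoding by
default with +64 available for legacy data. Paired-end mates are treated as
independent records; read merging, trimming, and alignment-coordinate
deduplication are out of scope.

## Alphabet generality

The algorithm is not DNA-specific: `Alphabet.build` accepts any symbol set
plus one wildcard (always stored in the last slot), e.g. amino acids with
`X`. The shipped default and all tests use `{A,C,G,T,N}`. IUPAC partial-
ambiguity codes (R, Y, S, …) are *not* partial wildcards — the model has
exactly one wildcard — so they are rejected as invalid symbols, or coerced
to `N` under the `coerce_unknown` flag. Input is uppercased on ingest.

## Simulator

The generator emulates PCR duplication with ambiguous calls: draw
`n_parents` distinct random sequences (rejection sampling enforces
uniqueness; only relevant at toy lengths), sample `n_reads` parents
uniformly with replacement, then mask exactly `n_mask` distinct positions
per read (uniformly chosen) to `N`. Reads sharing a parent are duplicates
by construction, so the true deduplicated size — the number of distinct
parents sampled — is known exactly. Defaults are 200-bp reads with as many
parents as reads, mirroring the benchmark grid of lengths
{30, 100, 150, 200} and N% {1, 5, 10, 20}.

When `n_reads == n_parents == n`, the expected sampled-parent fraction is
1 − (1 − 1/n)ⁿ → 1 − e⁻¹ ≈ 63.2%, and the property test checks the
empirical fraction against that within three standard errors.

What the simulator does **not** model: substitution/indel sequencing
errors, PCR amplification bias, quality-score profiles along the read
(masks are uniform in position, whereas real quality decays toward the
3′ end, and wildcard position affects trie cost), or length variation.
Passing the recovery tests therefore shows the algorithms are exact under
the stated duplication model, not that masking at any particular Q
threshold is the right call on a given library.

## Problem sizes and numerical choices

The shipped benchmarks and the acceptance script run at n ∈ {10², 10³,
10⁴} reads (200 bp, 5% N for scaling; 1% N for recovery), with the
quadratic pairwise baseline included at every size — large enough that the
log-log slope of the pairwise comparison count sits at its asymptotic ~2
and the trie's node-visit slope stays near 1.1, and a package user can
rerun everything in about a minute. Slopes are ordinary least-squares fits
of log₁₀(work) on log₁₀(n). Replicate seeds derive from the user seed via
`numpy` `SeedSequence`, so every table is a pure function of its inputs.
Degenerate inputs are defined, not special-cased: empty input gives an
empty result, an all-wildcard read matches any stored read of its length,
and re-adding a stored sequence is a no-op.

## Known limitations

* Greedy ascending-N MIS is a preference, not an optimum: it does not
  minimize (or maximize) the representative count over all MIS.
* A single wildcard symbol; no mismatch-tolerant or quality-weighted
  equivalence (summing error probabilities across mismatches would change
  the equivalence structure entirely).
* The trie trades memory for speed — it stores one node per base of every
  admitted unique sequence — and supports no deletion or serialization.
* For inputs much larger than ~10⁶ reads, splitting into non-overlapping
  groups (by prefix, locus, or V/J call) before deduplication is the
  practical route; the package does not do this for you.
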