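"""End-to-end deduplication: trie-based greedy admission plus two baselines.

Deduplicating under the wildcard equivalence is a maximal-independent-set
(MIS) problem on the equivalence graph: the retained representatives are
pairwise non-equivalent, and every removed read is equivalent to its
representative.  An MIS is not unique — the toy graph TAC–TNC–TGC has both
{TAC, TGC} and {TNC} — so all methods here fix the same preference: reads
are processed in ascending order of wildcard count (ties keep input order),
which favours the least-ambiguous reads as representatives.

Three methods share that preprocessing:

``dedup_trie``
    Greedy admission with membership tested against a wildcard-aware trie.
``dedup_pairwise``
    Same greedy admission, membership tested by scanning the admitted list
    with the equivalence predicate (the progressive pairwise baseline; it
    doubles as the reference oracle in tests).
``dedup_exact``
    Literal string collapsing only — the wildcard is treated as a fifth
    letter, so reads differing only at ambiguous positions stay distinct.
    This is the fast hash-based behaviour most tools implement, and it
    inflates the deduplicated set whenever wildcards are present.

Exact collapsing always runs first (identical strings never need a second
equivalence check), and the collapsed group then travels as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .alphabet import DNA, Alphabet, SeqRecord, _equiv, ensure_counts
from .trie import Trie

Method = Literal["trie", "pairwise", "exact"]


@dataclass
class DedupStats:
    """Work counters: equivalence calls (pairwise) and trie node visits."""

    comparisons: int = 0
    node_visits: int = 0
    nodes_allocated: int = 0


@dataclass
class DedupResult:
    """Outcome of one deduplication run.

    ``representatives`` are in admission order.  ``assignment`` maps every
    input read id to its representative's read id (representatives map to
    themselves); ``multiplicity`` counts how many inputs each representative
    stands for, so its values sum to the input size.
    """

    representatives: list[SeqRecord]
    assignment: dict[str, str]
    multiplicity: dict[str, int]
    stats: DedupStats = field(default_factory=DedupStats)
    method: Method = "trie"

    def __len__(self) -> int:
        return len(self.representatives)


def exact_collapse(
    records: Sequence[SeqRecord],
) -> tuple[list[SeqRecord], dict[str, str], dict[str, int]]:
    """Group literally identical sequences (wildcard treated as a distinct letter).

    Returns ``(uniques, assignment, multiplicity)`` where each group is keyed
    by its first-seen member (lowest input rank).  Runs before any
    equivalence-based method so identical strings are checked only once.
    """
    first_of: dict[str, SeqRecord] = {}
    assignment: dict[str, str] = {}
    multiplicity: dict[str, int] = {}
    uniques: list[SeqRecord] = []
    for rec in records:
        key = first_of.get(rec.seq)
        if key is None:
            first_of[rec.seq] = rec
            uniques.append(rec)
            assignment[rec.read_id] = rec.read_id
            multiplicity[rec.read_id] = 1
        else:
            assignment[rec.read_id] = key.read_id
            multiplicity[key.read_id] += 1
    return uniques, assignment, multiplicity


def sort_by_ambiguity(records: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Stable ascending sort on wildcard count; ties keep input order."""
    return sorted(records, key=lambda r: r.n_ambiguous)


def _finalize(
    reps: list[SeqRecord],
    rep_of_unique: dict[str, str],
    exact_assign: dict[str, str],
    exact_mult: dict[str, int],
    stats: DedupStats,
    method: Method,
) -> DedupResult:
    # Fold the exact-collapse groups into the equivalence-level assignment.
    assignment = {
        read_id: rep_of_unique[key] for read_id, key in exact_assign.items()
    }
    multiplicity: dict[str, int] = {}
    for key, count in exact_mult.items():
        rep = rep_of_unique[key]
        multiplicity[rep] = multiplicity.get(rep, 0) + count
    return DedupResult(reps, assignment, multiplicity, stats, method)


def dedup_trie(
    records: Sequence[SeqRecord],
    alphabet: Alphabet = DNA,
    presorted: bool = False,
) -> DedupResult:
    """Greedy MIS deduplication with trie-backed membership tests.

    Each read (after exact collapsing and the ascending-wildcard sort) is
    searched against the trie of admitted sequences; on a miss it is admitted
    and inserted, on a hit its whole exact-duplicate group is assigned to the
    earliest-admitted equivalent representative.  ``presorted=True`` skips
    the sort and honours the caller's order — greedy MIS results are
    order-dependent, and forcing an ambiguous read first yields the other
    MIS flavour (admitting TNC first collapses TAC and TGC onto it).
    """
    ensure_counts(records, alphabet)
    uniques, exact_assign, exact_mult = exact_collapse(records)
    ordered = uniques if presorted else sort_by_ambiguity(uniques)

    trie = Trie(alphabet)
    admission: dict[str, int] = {}  # stored seq -> admission index
    rep_id_of_seq: dict[str, str] = {}
    reps: list[SeqRecord] = []
    rep_of_unique: dict[str, str] = {}
    for rec in ordered:
        matches = trie.find_matches(rec.seq)
        if not matches:
            trie.add(rec.seq)
            admission[rec.seq] = len(reps)
            rep_id_of_seq[rec.seq] = rec.read_id
            reps.append(rec)
            rep_of_unique[rec.read_id] = rec.read_id
        else:
            best = min(matches, key=admission.__getitem__)
            rep_of_unique[rec.read_id] = rep_id_of_seq[best]

    stats = DedupStats(
        node_visits=trie.stats.node_visits,
        nodes_allocated=trie.stats.nodes_allocated,
    )
    return _finalize(reps, rep_of_unique, exact_assign, exact_mult, stats, "trie")


def dedup_pairwise(
    records: Sequence[SeqRecord],
    alphabet: Alphabet = DNA,
    presorted: bool = False,
) -> DedupResult:
    """Progressive pairwise deduplication (the reference baseline).

    Identical preprocessing and greedy admission as :func:`dedup_trie`, but
    membership is tested by scanning the admitted list in admission order
    with the equivalence predicate, stopping at the first match — which is by
    construction the earliest-admitted equivalent representative.
    """
    ensure_counts(records, alphabet)
    uniques, exact_assign, exact_mult = exact_collapse(records)
    ordered = uniques if presorted else sort_by_ambiguity(uniques)

    wc = alphabet.wildcard
    stored: list[tuple[str, str]] = []  # (seq, rep read_id) in admission order
    reps: list[SeqRecord] = []
    rep_of_unique: dict[str, str] = {}
    stats = DedupStats()
    for rec in ordered:
        seq = rec.seq
        hit = None
        n = 0
        for s, rid in stored:
            n += 1
            if _equiv(seq, s, wc):
                hit = rid
                break
        stats.comparisons += n
        if hit is None:
            stored.append((seq, rec.read_id))
            reps.append(rec)
            rep_of_unique[rec.read_id] = rec.read_id
        else:
            rep_of_unique[rec.read_id] = hit
    return _finalize(reps, rep_of_unique, exact_assign, exact_mult, stats, "pairwise")


def dedup_exact(
    records: Sequence[SeqRecord],
    alphabet: Alphabet = DNA,
) -> DedupResult:
    """Literal exact-matching deduplication (wildcard is a distinct letter)."""
    ensure_counts(records, alphabet)
    uniques, exact_assign, exact_mult = exact_collapse(records)
    rep_of_unique = {u.read_id: u.read_id for u in uniques}
    return _finalize(
        list(uniques), rep_of_unique, exact_assign, exact_mult, DedupStats(), "exact"
    )


def dedup(
    records: Sequence[SeqRecord],
    method: Method = "trie",
    alphabet: Alphabet = DNA,
    presorted: bool = False,
) -> DedupResult:
    """Dispatch to one of the three deduplication methods."""
    if method == "trie":
        return dedup_trie(records, alphabet, presorted)
    if method == "pairwise":
        return dedup_pairwise(records, alphabet, presorted)
    if method == "exact":
        return dedup_exact(records, alphabet)
    raise ValueError(f"unknown method {method!r}")
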