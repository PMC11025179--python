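"""Alphabets, sequence records, and the wildcard-tolerant equivalence relation.

Two same-length sequences are *equivalent* when every position either agrees
literally or carries the wildcard symbol on at least one side.  The wildcard
models an ambiguous base call ('N' for DNA): it may stand for any symbol, so
reads that differ only at low-quality positions are treated as duplicates of
one another.  The relation is reflexive and symmetric but NOT transitive
(e.g. TAC ~ TNC and TNC ~ TGC, yet TAC and TGC differ), which is why
deduplication under it is a maximal-independent-set problem rather than a
simple partition into groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import InvalidSymbolError


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol set with one designated wildcard.

    The wildcard always occupies the LAST slot index.  ``index_of`` is the
    single shared symbol->slot table used by every trie node (the
    restricted-dictionary layout): nodes store children in a plain list and
    look up slots through this one mapping instead of carrying a dict each.

    Parameters
    ----------
    symbols:
        Unique single characters, wildcard last.
    wildcard:
        The ambiguous symbol; must equal ``symbols[-1]``.
    """

    symbols: tuple[str, ...]
    wildcard: str
    index_of: dict[str, int] = field(compare=False, repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("alphabet symbols must be single characters")
        if self.wildcard != self.symbols[-1]:
            raise ValueError("the wildcard must occupy the last alphabet slot")
        object.__setattr__(
            self, "index_of", {s: i for i, s in enumerate(self.symbols)}
        )
        object.__setattr__(self, "_symbol_set", frozenset(self.symbols))

    @classmethod
    def build(cls, regular: str, wildcard: str = "N") -> "Alphabet":
        """Build an alphabet from its regular symbols plus a wildcard (kept last)."""
        regular = regular.upper()
        wildcard = wildcard.upper()
        syms = tuple(c for c in regular if c != wildcard) + (wildcard,)
        return cls(symbols=syms, wildcard=wildcard)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def wildcard_index(self) -> int:
        return len(self.symbols) - 1

    def __contains__(self, char: str) -> bool:
        return char in self._symbol_set  # type: ignore[attr-defined]


#: The default DNA alphabet: A, C, G, T with ambiguous base N as the wildcard.
DNA = Alphabet.build("ACGT", "N")


@dataclass
class SeqRecord:
    """One sequencing read.

    Attributes
    ----------
    read_id:
        Record identifier (FASTQ/FASTA header token).
    seq:
        Uppercase sequence over the alphabet.
    quals:
        Optional per-base Phred scores, same length as ``seq``.
    n_ambiguous:
        Cached count of wildcard symbols; filled lazily by
        :func:`count_ambiguous` callers when ``None``.
    input_rank:
        0-based position in the input stream; used for stable tie-breaking.
    """

    read_id: str
    seq: str
    quals: Optional[list[int]] = None
    n_ambiguous: Optional[int] = None
    input_rank: int = 0

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.seq):
            from .errors import FormatError

            raise FormatError(
                f"record {self.read_id!r}: {len(self.quals)} quality values "
                f"for {len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


def validate_seq(seq: str, alphabet: Alphabet = DNA, context: str = "") -> None:
    """Raise :class:`InvalidSymbolError` naming the first offending character."""
    allowed = alphabet._symbol_set  # type: ignore[attr-defined]
    if set(seq) <= allowed:
        return
    for i, c in enumerate(seq):
        if c not in allowed:
            raise InvalidSymbolError(c, i, context)


def _equiv(a: str, b: str, wildcard: str) -> bool:
    # Hot path: no validation; callers validate once at ingest.
    if len(a) != len(b):
        return False
    if a == b:
        return True
    for x, y in zip(a, b):
        if x != y and x != wildcard and y != wildcard:
            return False
    return True


def seq_equivalent(a: str, b: str, alphabet: Alphabet = DNA) -> bool:
    """True iff ``a`` and ``b`` have equal length and agree at every position
    up to the wildcard.

    Symmetric and reflexive, but not transitive.
    """
    validate_seq(a, alphabet)
    validate_seq(b, alphabet)
    return _equiv(a, b, alphabet.wildcard)


def count_ambiguous(seq: str, alphabet: Alphabet = DNA) -> int:
    """Number of wildcard symbols in ``seq`` (validates the sequence)."""
    validate_seq(seq, alphabet)
    return seq.count(alphabet.wildcard)


def normalize(seq: str, alphabet: Alphabet = DNA, coerce_unknown: bool = False) -> str:
    """Uppercase ``seq``; optionally convert out-of-alphabet characters to the wildcard.

    Pure transform: with ``coerce_unknown=False`` unknown characters pass
    through unchanged and are caught by downstream validation.
    """
    seq = seq.upper()
    allowed = alphabet._symbol_set  # type: ignore[attr-defined]
    if coerce_unknown and not set(seq) <= allowed:
        wc = alphabet.wildcard
        seq = "".join(c if c in allowed else wc for c in seq)
    return seq


def ensure_counts(records: Sequence[SeqRecord], alphabet: Alphabet = DNA) -> None:
    """Validate every record and fill in missing ``n_ambiguous`` caches."""
    for rec in records:
        validate_seq(rec.seq, alphabet, context=f"read {rec.read_id!r}")
        if rec.n_ambiguous is None:
            rec.n_ambiguous = rec.seq.count(alphabet.wildcard)
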