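"""Prefix tree over a fixed alphabet with wildcard-aware search.

The trie stores the already-admitted (deduplicated) sequences.  Each node
keeps a fixed-size list with one slot per alphabet symbol — the wildcard
slot last — plus a terminal flag marking that a stored sequence ends there.
Slot indices come from the single shared ``Alphabet.index_of`` table, so a
node is just a small list and a bool (``__slots__``, no per-instance dict):
that per-symbol-slot layout is what keeps a million-node trie affordable.

Search descends one level per query position.  A regular query symbol tries
its own slot and then the wildcard slot (a stored 'N' matches anything); a
wildcard query symbol tries every occupied slot, regular symbols first,
wildcard last.  Branch order is fixed so both results and visit counters are
deterministic.  The traversal uses an explicit stack, so query length is not
limited by the interpreter recursion limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .alphabet import DNA, Alphabet
from .errors import InvalidSymbolError


class TrieNode:
    """One trie node: per-symbol child slots plus a terminal flag."""

    __slots__ = ("children", "is_terminal")

    def __init__(self, n_slots: int):
        self.children: list[Optional["TrieNode"]] = [None] * n_slots
        self.is_terminal = False


@dataclass
class TrieStats:
    """Monotone counters: a hardware-independent proxy for search cost.

    ``node_visits`` counts nodes touched by searches (the root included);
    ``nodes_allocated`` counts nodes created, root included.
    """

    node_visits: int = 0
    nodes_allocated: int = 0


class Trie:
    """A trie of stored sequences supporting wildcard-equivalent lookup."""

    def __init__(self, alphabet: Alphabet = DNA):
        self.alphabet = alphabet
        self.root = TrieNode(len(alphabet))
        self.stats = TrieStats(nodes_allocated=1)

    # -- helpers ---------------------------------------------------------

    def _encode(self, seq: str) -> list[int]:
        index_of = self.alphabet.index_of
        try:
            return [index_of[c] for c in seq]
        except KeyError:
            for i, c in enumerate(seq):
                if c not in index_of:
                    raise InvalidSymbolError(c, i) from None
            raise  # pragma: no cover

    # -- mutation --------------------------------------------------------

    def add(self, seq: str) -> None:
        """Insert ``seq``, creating missing nodes; idempotent for repeats.

        The caller is responsible for having checked that ``seq`` is not
        wildcard-equivalent to any stored sequence (the greedy admission
        contract); ``add`` itself only stores.
        """
        n_slots = len(self.alphabet)
        node = self.root
        for s in self._encode(seq):
            child = node.children[s]
            if child is None:
                child = TrieNode(n_slots)
                node.children[s] = child
                self.stats.nodes_allocated += 1
            node = child
        node.is_terminal = True

    # -- queries ---------------------------------------------------------

    def search(self, seq: str, pos: int = 0) -> bool:
        """True iff some stored sequence is wildcard-equivalent to ``seq[pos:]``.

        Short-circuits on the first matching branch.  Every node popped from
        the traversal stack counts one ``node_visits`` tick; a wildcard-free
        query against wildcard-free content therefore costs at most
        ``len(seq) - pos + 1`` visits (a single root-to-leaf walk).
        """
        if not 0 <= pos <= len(seq):
            raise ValueError(f"pos={pos} outside [0, {len(seq)}]")
        q = self._encode(seq)
        L = len(seq)
        wc = self.alphabet.wildcard_index
        visits = 0
        stack = [(self.root, pos)]
        found = False
        while stack:
            node, p = stack.pop()
            visits += 1
            if p == L:
                if node.is_terminal:
                    found = True
                    break
                continue
            children = node.children
            qi = q[p]
            if qi == wc:
                # query wildcard: all occupied slots, regular first, wildcard last
                for s in range(len(children) - 1, -1, -1):
                    child = children[s]
                    if child is not None:
                        stack.append((child, p + 1))
            else:
                child = children[wc]
                if child is not None:
                    stack.append((child, p + 1))
                child = children[qi]
                if child is not None:
                    stack.append((child, p + 1))
        self.stats.node_visits += visits
        return found

    def find_matches(self, seq: str) -> list[str]:
        """All stored sequences wildcard-equivalent to ``seq``, in DFS slot order.

        Unlike :meth:`search` this does not short-circuit; the dedup pipeline
        uses it to pick a canonical (earliest-admitted) representative when a
        query happens to match more than one stored sequence.
        """
        q = self._encode(seq)
        L = len(seq)
        wc = self.alphabet.wildcard_index
        symbols = self.alphabet.symbols
        visits = 0
        path = [0] * L
        # frames carry the slot index used to reach the node (-1 for root)
        stack: list[tuple[TrieNode, int, int]] = [(self.root, 0, -1)]
        out: list[str] = []
        while stack:
            node, p, via = stack.pop()
            visits += 1
            if via >= 0:
                path[p - 1] = via
            if p == L:
                if node.is_terminal:
                    out.append("".join(symbols[i] for i in path))
                continue
            children = node.children
            qi = q[p]
            if qi == wc:
                for s in range(len(children) - 1, -1, -1):
                    child = children[s]
                    if child is not None:
                        stack.append((child, p + 1, s))
            else:
                child = children[wc]
                if child is not None:
                    stack.append((child, p + 1, wc))
                child = children[qi]
                if child is not None:
                    stack.append((child, p + 1, qi))
        self.stats.node_visits += visits
        return out

    # -- introspection ---------------------------------------------------

    def nodes(self) -> Iterator[TrieNode]:
        """Iterate over all nodes (root first, DFS)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in node.children:
                if child is not None:
                    stack.append(child)

    def __contains__(self, seq: str) -> bool:
        return self.search(seq)


def trie_add(trie: Trie, seq: str) -> None:
    """Functional spelling of :meth:`Trie.add`."""
    trie.add(seq)


def trie_search(trie: Trie, seq: str, pos: int = 0) -> bool:
    """Functional spelling of :meth:`Trie.search`."""
    return trie.search(seq, pos)
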